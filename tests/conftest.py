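import logging

from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# peak-shoulder and ingest warnings are expected noise in the recovery tests
logging.getLogger("karyosurvey").setLevel(logging.ERROR)
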