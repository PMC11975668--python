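"""Karyotype statistics: worked examples, invariants, and an independent
brute-force oracle for the whole-karyotype summary."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from karyosurvey import karyotype as kt
from karyosurvey.karyotype import (
    ArmMeasurement,
    KaryotypeInput,
    KaryotypePair,
    KaryotypeError,
)
from karyosurvey.synth import KaryotypeSpec, gen_karyotype_measurements

# ---------------------------------------------------------------------------
# strategies / helpers
# ---------------------------------------------------------------------------

arm = st.floats(min_value=0.1, max_value=50.0, allow_nan=False, allow_infinity=False)


@st.composite
def karyotype_pairs(draw, min_pairs=1, max_pairs=15):
    n = draw(st.integers(min_pairs, max_pairs))
    pairs = []
    for i in range(n):
        short = draw(arm)
        long_ = short * draw(st.floats(1.0, 12.0))
        pairs.append(KaryotypePair(i + 1, short, long_))
    return pairs


def pairs_from(arms):
    return [KaryotypePair(i + 1, s, l) for i, (s, l) in enumerate(arms)]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_aggregate_pairs_means_over_cells():
    ms = [
        ArmMeasurement("c1", 1, 1.0, 2.0),
        ArmMeasurement("c2", 1, 3.0, 4.0),
    ]
    (pair,) = kt.aggregate_pairs(ms)
    assert (pair.mean_short_um, pair.mean_long_um) == (2.0, 3.0)


def test_aggregate_pairs_single_measurement_identity():
    (pair,) = kt.aggregate_pairs([ArmMeasurement("c1", 1, 1.5, 1.5)])
    assert (pair.mean_short_um, pair.mean_long_um) == (1.5, 1.5)


def test_aggregate_pairs_names_missing_pair():
    ms = [ArmMeasurement("c1", 1, 1, 2), ArmMeasurement("c1", 3, 1, 2)]
    with pytest.raises(KaryotypeError, match=r"\[2\]"):
        kt.aggregate_pairs(ms)


def test_aggregate_recovers_generator_truth_within_3_se():
    true_pairs = [(1.0 + 0.3 * i, 2.0 + 0.5 * i) for i in range(13)]
    spec = KaryotypeSpec(pairs=true_pairs, noise_cv=0.02, n_cells=5, seed=42)
    ms, truth = gen_karyotype_measurements(spec)
    pairs = kt.aggregate_pairs(ms)
    for pair, (s_true, l_true) in zip(pairs, truth["pairs"]):
        se_s = 0.02 * s_true / math.sqrt(5)
        se_l = 0.02 * l_true / math.sqrt(5)
        assert abs(pair.mean_short_um - s_true) <= 3 * se_s
        assert abs(pair.mean_long_um - l_true) <= 3 * se_l


def test_load_measurements_swaps_and_rejects(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text(
        "cell_id\tpair_id\tshort_um\tlong_um\n"
        "c1\t1\t2.0\t1.0\n"   # inverted -> swap
        "c1\t2\t-1.0\t2.0\n"  # non-positive -> reject
        "c1\t2\t1.0\t2.0\n"
    )
    ms, report = kt.load_measurements(path)
    assert report == {"n_rows": 3, "n_rejected": 1, "n_swapped": 1, "n_clamped": 0}
    assert ms[0].short_um == 1.0 and ms[0].long_um == 2.0


def test_load_measurements_telocentric_clamp(tmp_path):
    path = tmp_path / "m.tsv"
    path.write_text(
        "cell_id\tpair_id\tshort_um\tlong_um\n"
        "c1\t1\t0.0\t5.0\n"
    )
    ms, report = kt.load_measurements(path)  # default: reject
    assert ms == [] and report["n_rejected"] == 1
    ms, report = kt.load_measurements(path, clamp_telocentric=0.1)
    assert report["n_clamped"] == 1
    assert kt.classify_centromere(kt.arm_ratio(kt.aggregate_pairs(ms)[0])) == "t"


# ---------------------------------------------------------------------------
# per-pair statistics
# ---------------------------------------------------------------------------

def test_relative_length_examples():
    rl = kt.relative_length(pairs_from([(1.0, 2.0), (3.0, 4.0)]))  # totals 3, 7
    assert rl == pytest.approx([30.0, 70.0])
    rl = kt.relative_length(pairs_from([(1.0, 1.0)] * 4))
    assert rl == pytest.approx([25.0] * 4)


@given(karyotype_pairs())
def test_relative_length_sums_to_100(pairs):
    assert math.isclose(sum(kt.relative_length(pairs)), 100.0, abs_tol=1e-9)


def test_relative_length_matches_ratio_oracle():
    rng = np.random.default_rng(7)
    arms = [(s, s + d) for s, d in zip(rng.uniform(0.5, 5, 13), rng.uniform(0, 5, 13))]
    pairs = pairs_from(arms)
    total = sum(s + l for s, l in arms)
    expected = [100.0 * (s + l) / total for s, l in arms]
    assert kt.relative_length(pairs) == pytest.approx(expected, abs=1e-9)


def test_arm_ratio_examples():
    assert kt.arm_ratio(KaryotypePair(1, 2.0, 2.0)) == 1.0
    # inside the printed female AR range 3.02-3.65 of the subtelocentric karyotype
    assert kt.arm_ratio(KaryotypePair(1, 1.0, 3.65)) == pytest.approx(3.65)


@given(karyotype_pairs(max_pairs=5))
def test_arm_ratio_algebraic_inversion(pairs):
    for p in pairs:
        assert kt.arm_ratio(p) * p.mean_short_um == pytest.approx(p.mean_long_um)


@pytest.mark.parametrize(
    "ar, expected",
    [
        (1.0, "m"),
        (1.69, "m"),
        (1.7, "sm"),   # left-closed boundary
        (2.99, "sm"),
        (3.0, "st"),
        (3.02, "st"),  # bottom of the all-st female range
        (6.99, "st"),
        (7.0, "t"),    # left-closed boundary
        (12.20, "t"),  # top of the male range whose formula contains 6t
    ],
)
def test_classify_centromere(ar, expected):
    assert kt.classify_centromere(ar) == expected


def test_classify_centromere_rejects_sub_unity():
    with pytest.raises(KaryotypeError):
        kt.classify_centromere(0.99)


@given(st.floats(1.0, 20.0), st.floats(1.0, 20.0))
def test_classify_centromere_monotone(a, b):
    order = {c: i for i, c in enumerate(kt.CENTROMERE_CLASSES)}
    lo, hi = sorted([a, b])
    assert order[kt.classify_centromere(lo)] <= order[kt.classify_centromere(hi)]


# ---------------------------------------------------------------------------
# karyotype formula
# ---------------------------------------------------------------------------

def test_karyotype_formula_published_shapes():
    assert kt.karyotype_formula(["m"] * 7 + ["sm"] * 6, two_n=26) == "14m+12sm"
    assert kt.karyotype_formula(["st"] * 10, two_n=20) == "20st"
    assert kt.karyotype_formula(["m"], two_n=2) == "2m"


def test_karyotype_formula_with_univalents():
    # male X1X2O: 2 stated univalents outside the measured complement
    assert kt.karyotype_formula(["m"] * 5 + ["sm"] * 6, two_n=24,
                                unpaired_sex_chromosomes=2) == "10m+12sm"
    # with measured univalent classes, they enter the counts
    assert kt.karyotype_formula(["m"] * 5 + ["sm"] * 6, two_n=24,
                                unpaired_sex_chromosomes=2,
                                unpaired_classes=["m", "m"]) == "12m+12sm"


def test_karyotype_formula_inconsistent_two_n():
    with pytest.raises(KaryotypeError):
        kt.karyotype_formula(["m", "sm"], two_n=6)


@given(st.lists(st.sampled_from(kt.CENTROMERE_CLASSES), min_size=1, max_size=15))
def test_karyotype_formula_counts_sum_to_2n(classes):
    two_n = 2 * len(classes)
    formula = kt.karyotype_formula(classes, two_n)
    total = sum(int("".join(ch for ch in term if ch.isdigit()))
                for term in formula.split("+"))
    assert total == two_n


# ---------------------------------------------------------------------------
# asymmetry
# ---------------------------------------------------------------------------

def test_asymmetry_coefficient_examples():
    assert kt.asymmetry_coefficient(pairs_from([(1, 1), (2, 2)])) == pytest.approx(50.0)
    # (long, short) = (9,1),(8,2),(7,3) -> 100*24/30
    assert kt.asymmetry_coefficient(pairs_from([(1, 9), (2, 8), (3, 7)])) == pytest.approx(80.0)
    # telocentric limit: vanishing short arms -> approaches 100
    assert kt.asymmetry_coefficient(pairs_from([(1e-9, 5.0)])) == pytest.approx(100.0, abs=1e-4)


@given(karyotype_pairs())
def test_asymmetry_coefficient_range_and_equality_condition(pairs):
    ask = kt.asymmetry_coefficient(pairs)
    assert 50.0 - 1e-9 <= ask <= 100.0
    if all(p.mean_long_um == p.mean_short_um for p in pairs):
        assert math.isclose(ask, 50.0)
    if any(p.mean_long_um > p.mean_short_um for p in pairs):
        assert ask > 50.0


# ---------------------------------------------------------------------------
# Stebbins type and sex-chromosome arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ls, prop, expected",
    [
        (1.50, 0.15, "2A"),
        (1.90, 0.13, "2A"),
        (1.99, 1.00, "4A"),
        (1.71, 1.00, "4A"),
        (1.0, 0.0, "1A"),
        (2.5, 0.6, "3B"),
        (4.5, 0.2, "2C"),
    ],
)
def test_stebbins_type(ls, prop, expected):
    assert kt.stebbins_type(ls, prop) == expected


def test_stebbins_type_rejects_out_of_range():
    with pytest.raises(KaryotypeError):
        kt.stebbins_type(0.9, 0.5)
    with pytest.raises(KaryotypeError):
        kt.stebbins_type(1.5, 1.2)


@pytest.mark.parametrize(
    "male_two_n, scs, female_two_n, bivalents",
    [
        (24, "X1X2O", 26, 11),
        (18, "X1X2O", 20, 8),
        (21, "X1X2X3O", 24, 9),
        (23, "XO", 24, 11),
    ],
)
def test_scs_arithmetic(male_two_n, scs, female_two_n, bivalents):
    female, config = kt.scs_arithmetic(male_two_n, scs)
    assert female == female_two_n
    assert config.bivalents == bivalents
    assert config.sex_univalents == kt.SCS_X_COUNT[scs]
    assert 2 * config.bivalents + config.sex_univalents == male_two_n


def test_scs_arithmetic_meiotic_formula():
    _, config = kt.scs_arithmetic(24, "X1X2O")
    assert config.n_formula == "n = 11 + X1X2"


def test_scs_arithmetic_parity_violation():
    with pytest.raises(KaryotypeError, match="even"):
        kt.scs_arithmetic(23, "X1X2O")


@given(st.integers(1, 30), st.sampled_from(list(kt.SCS_X_COUNT)))
def test_scs_arithmetic_round_trip(bivalents, scs):
    n_x = kt.SCS_X_COUNT[scs]
    male = 2 * bivalents + n_x
    female, _ = kt.scs_arithmetic(male, scs)
    assert female - male == n_x


# ---------------------------------------------------------------------------
# whole-karyotype summary against a brute-force oracle
# ---------------------------------------------------------------------------

def _oracle_summary(arms):
    """Independent plain-arithmetic recomputation of every summary field."""
    totals = [s + l for s, l in arms]
    ars = [l / s for s, l in arms]

    def cls(ar):
        if ar < 1.7:
            return "m"
        if ar < 3.0:
            return "sm"
        if ar < 7.0:
            return "st"
        return "t"

    classes = [cls(a) for a in ars]
    prop = sum(1 for a in ars if a > 2) / len(ars)
    ls = max(totals) / min(totals)
    num = "1" if prop == 0 else "2" if prop <= 0.5 else "3" if prop <= 0.99 else "4"
    let = "A" if ls < 2 else "B" if ls <= 4 else "C"
    counts = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 2
    kf = "+".join(f"{counts[c]}{c}" for c in ("m", "sm", "st", "t") if c in counts)
    return {
        "rl": [100 * t / sum(totals) for t in totals],
        "ar": ars,
        "classes": classes,
        "cl": (min(totals), max(totals)),
        "ml": sum(totals) / len(totals),
        "mar": sum(ars) / len(ars),
        "ls": ls,
        "ask": 100 * sum(l for _, l in arms) / sum(totals),
        "prop": prop,
        "kt": num + let,
        "kf": kf,
    }


def test_summarize_karyotype_trivial_single_pair():
    inp = KaryotypeInput("sp", "female", "X1X2O", pairs_from([(1.0, 1.0)]))
    s = kt.summarize_karyotype(inp)
    assert s.ml_um == 2.0
    assert s.ls == 1.0
    assert s.ask_pct == pytest.approx(50.0)
    assert s.kf == "2m"
    assert s.stebbins == "1A"


def test_summarize_karyotype_matches_oracle_on_random_karyotypes():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        n = int(rng.integers(1, 16))
        shorts = rng.uniform(0.2, 8.0, n)
        longs = shorts * rng.uniform(1.0, 12.0, n)
        arms = list(zip(shorts, longs))
        inp = KaryotypeInput("sp", "female", "X1X2O", pairs_from(arms))
        s = kt.summarize_karyotype(inp)
        o = _oracle_summary(arms)
        assert s.rl_pct == pytest.approx(o["rl"])
        assert s.ar == pytest.approx(o["ar"])
        assert s.centromere_class == o["classes"]
        assert s.cl_range_um == pytest.approx(o["cl"])
        assert s.ml_um == pytest.approx(o["ml"])
        assert s.mar == pytest.approx(o["mar"])
        assert s.ls == pytest.approx(o["ls"])
        assert s.ask_pct == pytest.approx(o["ask"])
        assert s.prop_ar_gt2 == pytest.approx(o["prop"])
        assert s.stebbins == o["kt"]
        assert s.kf == o["kf"]


def test_centromere_class_recovery_from_noisy_measurements():
    """5 noisy cells recover the true class whenever the true AR sits
    at least 0.1 from a Levan boundary."""
    rng = np.random.default_rng(5)
    boundaries = (1.7, 3.0, 7.0)
    true_pairs = []
    for _ in range(30):
        ar = float(rng.uniform(1.0, 9.0))
        if min(abs(ar - b) for b in boundaries) < 0.1:
            continue
        short = float(rng.uniform(0.5, 4.0))
        true_pairs.append((short, short * ar))
    spec = KaryotypeSpec(pairs=true_pairs, noise_cv=0.02, n_cells=5, seed=99)
    ms, _ = gen_karyotype_measurements(spec)
    pairs = kt.aggregate_pairs(ms)
    for pair, (s_true, l_true) in zip(pairs, true_pairs):
        assert kt.classify_centromere(kt.arm_ratio(pair)) == \
            kt.classify_centromere(l_true / s_true)


# ---------------------------------------------------------------------------
# idiogram
# ---------------------------------------------------------------------------

def test_idiogram_signs_and_tsv_round_trip(tmp_path):
    pairs = pairs_from([(1.0, 2.0), (1.5, 1.5)])
    df = kt.idiogram_data(pairs)
    assert df.loc[0, "short_um"] == 1.0 and df.loc[0, "long_um"] == -2.0
    assert abs(df.loc[1, "short_um"]) == abs(df.loc[1, "long_um"])
    path = tmp_path / "idiogram.tsv"
    df.to_csv(path, sep="\t", index=False)
    back = pd.read_csv(path, sep="\t")
    pd.testing.assert_frame_equal(df, back)
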