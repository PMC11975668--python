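"""Flow-cytometry genome sizing against an internal reference standard.

The estimator is the classical propidium-iodide ratio method: the mean
fluorescence of the sample's G1 (2C) peak divided by that of a co-run
internal reference of known DNA content gives the sample's 2C value in
picograms, converted to megabases with 1 pg = 978 Mb. Quality gates follow
standard practice: at least 10,000 nuclei per acquisition and a peak
coefficient of variation of at most 5%; the final size is the mean of
(typically three) biological replicates.

Event lists are plain per-nucleus fluorescence intensities (one channel),
read from TSV/CSV. Peak location is mode-anchored: the histogram mode,
a robust (MAD-based) spread estimate, and the mean of events within
mode ± 2 robust sigma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "EventSet",
    "Peak",
    "QcResult",
    "GenomeSizeEstimate",
    "PG_TO_MB",
    "DEFAULT_REF_2C_PG",
    "load_events",
    "detect_g1_peak",
    "detect_costained_peaks",
    "qc_gate",
    "estimate_2c_pg",
    "pg_to_mb",
    "combine_replicates",
    "size_genome",
]

#: DNA mass to sequence length: 1 pg of double-stranded DNA ≈ 978 Mb.
PG_TO_MB = 978.0

#: 2C DNA content of the Solanum lycopersicum internal reference, pg.
DEFAULT_REF_2C_PG = 0.85


class FcmError(ValueError):
    """Unusable event data or peak structure."""


class AmbiguousPeaksError(FcmError):
    """Two candidate G1 peaks of comparable mass; cannot pick one."""

    def __init__(self, candidates):
        self.candidates = candidates
        desc = ", ".join(f"{c.mean_channel:.1f} ({c.n_events} events)" for c in candidates)
        super().__init__(f"ambiguous dominant peak; candidates: {desc}")


@dataclass
class EventSet:
    """Per-nucleus fluorescence intensities from one acquisition."""

    label: str
    intensities: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size == 0:
            raise FcmError(f"{self.label}: no events")
        if np.any(self.intensities <= 0):
            raise FcmError(f"{self.label}: non-positive intensities must be dropped on load")

    @property
    def n_events(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class Peak:
    """A detected fluorescence peak and its within-window statistics."""

    mean_channel: float
    cv_pct: float
    n_events: int
    window: tuple[float, float]


@dataclass(frozen=True)
class QcResult:
    passed: bool
    failures: tuple[str, ...]


@dataclass
class GenomeSizeEstimate:
    """Ratio-method genome size; replicate detail retained."""

    ratio: float
    c2_pg: float
    size_mb: float
    replicate_values: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------

def load_events(path: str | Path, fmt: str | None = None, column: str = "intensity",
                label: str | None = None) -> EventSet:
    """Read an event list from TSV/CSV (one ``intensity`` column, or a
    single headerless numeric column). Non-positive values are dropped
    and counted in ``n_dropped``."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "csv"
    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FcmError(f"cannot parse {path}: {exc}") from exc
    if column in df.columns:
        values = pd.to_numeric(df[column], errors="coerce").to_numpy()
    else:
        # headerless single column: first row was consumed as header
        df = pd.read_csv(path, sep=sep, header=None)
        if df.shape[1] != 1:
            raise FcmError(f"{path}: no {column!r} column and not single-column")
        values = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    values = values[~np.isnan(values)]
    keep = values > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("%s: dropped %d non-positive events", path, n_dropped)
    if keep.sum() == 0:
        raise FcmError(f"{path}: zero usable events")
    return EventSet(label=label or path.stem, intensities=values[keep], n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _window_stats(x: np.ndarray, mode: float) -> Peak:
    """Mode-anchored window: ±2·(1.4826·MAD) around the mode, then the
    plain mean/CV of events inside the window."""
    near = x[(x > 0.75 * mode) & (x < 1.25 * mode)]
    center = float(np.median(near))  # re-anchor: bin centers are quantized
    sigma = 1.4826 * np.median(np.abs(near - center))
    if sigma == 0:  # degenerate: (near-)constant events
        return Peak(mean_channel=center, cv_pct=0.0,
                    n_events=int(near.size), window=(center, center))
    lo, hi = center - 2 * sigma, center + 2 * sigma
    inside = x[(x >= lo) & (x <= hi)]
    mean = float(inside.mean())
    cv = 100.0 * float(inside.std(ddof=0)) / mean
    return Peak(mean_channel=mean, cv_pct=cv, n_events=int(inside.size),
                window=(float(lo), float(hi)))


def _candidate_peaks(events: EventSet, bins: int, smooth_bins: int,
                     debris_frac: float, min_prominence_frac: float) -> list[Peak]:
    x = events.intensities
    if np.unique(x).size == 1:
        v = float(x[0])
        return [Peak(mean_channel=v, cv_pct=0.0, n_events=x.size, window=(v, v))]
    x = x[x >= debris_frac * x.max()]
    if x.size == 0:
        raise FcmError(f"{events.label}: all events below the debris cutoff")
    hist, edges = np.histogram(x, bins=bins, range=(0.0, float(x.max())))
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(hist, kernel, mode="same")
    # zero-pad so a mode in the first/last bin is still a local maximum
    padded = np.concatenate(([0.0], smooth, [0.0]))
    idx, _ = find_peaks(padded, prominence=min_prominence_frac * smooth.max())
    idx = idx - 1
    if idx.size == 0:
        raise FcmError(f"{events.label}: no peak of sufficient prominence")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = [_window_stats(x, float(centers[i])) for i in idx]
    # merge candidates whose windows collapsed onto the same peak
    peaks.sort(key=lambda p: -p.n_events)
    distinct: list[Peak] = []
    for p in peaks:
        if all(abs(p.mean_channel - q.mean_channel)
               > 0.05 * max(p.mean_channel, q.mean_channel) for q in distinct):
            distinct.append(p)
    return distinct


def detect_g1_peak(events: EventSet, bins: int = 1024, smooth_bins: int = 5,
                   debris_frac: float = 0.02, min_prominence_frac: float = 0.05,
                   ambiguity_ratio: float = 0.9) -> Peak:
    """Locate the dominant (G1/2C) fluorescence peak.

    The histogram (``bins`` over [0, max], debris below ``debris_frac``·max
    excluded) is smoothed by a moving average and local maxima are ranked
    by event mass; the peak statistics are mode-anchored window means.
    Two top candidates within ``ambiguity_ratio`` of each other's mass
    raise :class:`AmbiguousPeaksError` listing them.
    """
    distinct = _candidate_peaks(events, bins, smooth_bins, debris_frac, min_prominence_frac)
    if len(distinct) > 1 and distinct[1].n_events >= ambiguity_ratio * distinct[0].n_events:
        raise AmbiguousPeaksError(distinct[:2])
    return distinct[0]


def detect_costained_peaks(events: EventSet, reference_is_smaller: bool = True,
                           **kwargs) -> tuple[Peak, Peak]:
    """Split a co-stained acquisition into (reference, sample) peaks.

    The two most massive distinct peaks are taken; the reference is the
    smaller-mean one unless ``reference_is_smaller`` is False.
    """
    distinct = _candidate_peaks(
        events,
        kwargs.get("bins", 1024),
        kwargs.get("smooth_bins", 5),
        kwargs.get("debris_frac", 0.02),
        kwargs.get("min_prominence_frac", 0.05),
    )
    if len(distinct) < 2:
        raise FcmError(f"{events.label}: expected two co-stained peaks, found {len(distinct)}")
    a, b = sorted(distinct[:2], key=lambda p: p.mean_channel)
    return (a, b) if reference_is_smaller else (b, a)


# ---------------------------------------------------------------------------
# quality gates and the ratio chain
# ---------------------------------------------------------------------------

def qc_gate(peak: Peak, n_total: int, max_cv_pct: float = 5.0,
            min_events: int = 10_000) -> QcResult:
    """Acquisition quality: ≥ ``min_events`` nuclei and CV ≤ ``max_cv_pct``."""
    failures = []
    if n_total < min_events:
        failures.append(f"events: {n_total} < required {min_events}")
    if peak.cv_pct > max_cv_pct:
        failures.append(f"CV: {peak.cv_pct:.2f}% > allowed {max_cv_pct}%")
    return QcResult(passed=not failures, failures=tuple(failures))


def estimate_2c_pg(sample_mean: float, ref_mean: float,
                   ref_2c_pg: float = DEFAULT_REF_2C_PG) -> float:
    """Sample 2C DNA content: (sample mean / reference mean) × reference 2C."""
    if sample_mean <= 0 or ref_mean <= 0:
        raise FcmError("peak means must be positive")
    return (sample_mean / ref_mean) * ref_2c_pg


def pg_to_mb(c2_pg: float) -> float:
    """Genome size in Mb from a 2C value in pg (1 pg = 978 Mb)."""
    if c2_pg <= 0:
        raise FcmError("2C value must be positive")
    return c2_pg * PG_TO_MB


def combine_replicates(estimates: Sequence[float]) -> float:
    """Final genome size: arithmetic mean over biological replicates."""
    if not len(estimates):
        raise FcmError("no replicate estimates")
    return float(np.mean(estimates))


def size_genome(samples: Sequence[EventSet], reference: EventSet | Sequence[EventSet],
                ref_2c_pg: float = DEFAULT_REF_2C_PG, max_cv_pct: float = 5.0,
                min_events: int = 10_000, enforce_qc: bool = True,
                **peak_kwargs) -> tuple[GenomeSizeEstimate, list[dict]]:
    """Full replicate pipeline: peaks → QC → ratio → pg → Mb → replicate mean.

    ``reference`` may be one EventSet shared by all replicates or one per
    replicate. Returns the combined estimate plus a per-replicate detail
    list (peaks, QC). With ``enforce_qc`` any gate failure raises.
    """
    refs = [reference] * len(samples) if isinstance(reference, EventSet) else list(reference)
    if len(refs) != len(samples):
        raise FcmError(f"{len(samples)} samples but {len(refs)} references")
    sizes, ratios, pgs, detail = [], [], [], []
    for s, r in zip(samples, refs):
        sp = detect_g1_peak(s, **peak_kwargs)
        rp = detect_g1_peak(r, **peak_kwargs)
        s_qc = qc_gate(sp, s.n_events, max_cv_pct, min_events)
        r_qc = qc_gate(rp, r.n_events, max_cv_pct, min_events)
        if enforce_qc and not (s_qc.passed and r_qc.passed):
            raise FcmError(
                f"QC failure for replicate {s.label!r}: "
                + "; ".join(s_qc.failures + r_qc.failures)
            )
        pg = estimate_2c_pg(sp.mean_channel, rp.mean_channel, ref_2c_pg)
        sizes.append(pg_to_mb(pg))
        ratios.append(sp.mean_channel / rp.mean_channel)
        pgs.append(pg)
        detail.append(
            {
                "sample": s.label,
                "reference": r.label,
                "sample_peak": sp,
                "reference_peak": rp,
                "sample_qc": s_qc,
                "reference_qc": r_qc,
                "ratio": ratios[-1],
                "c2_pg": pg,
                "size_mb": sizes[-1],
            }
        )
    est = GenomeSizeEstimate(
        ratio=float(np.mean(ratios)),
        c2_pg=float(np.mean(pgs)),
        size_mb=combine_replicates(sizes),
        replicate_values=sizes,
    )
    return est, detail
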