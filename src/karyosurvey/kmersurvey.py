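"""K-mer spectrum genome profiling: size, heterozygosity, duplication.

A genome survey from short reads proceeds by counting canonical k-mers
(k odd, default 19), histogramming their multiplicities into a
depth → distinct-k-mer spectrum, discarding the low-depth tail produced
by sequencing errors (depth < 5 by default), locating the homozygous
coverage peak, and applying

    genome size = total retained k-mer count / peak depth.

Heterozygosity is read off the half-depth component of a diploid
spectrum: with b the fraction of retained k-mer mass in the
heterozygous (half-depth) component, the per-base rate is
h = 1 − (1 − b)^(1/k), because a k-mer is heterozygous iff any of its
k bases overlaps a SNP. The duplication ratio is the fraction of
retained mass at depths above ``repeat_factor`` × peak (default 1.8),
i.e. k-mers present in more copies than the homozygous single-copy
complement.

Counting is exact and in memory (2-bit codes, numpy), streaming over
reads; it is intended for survey-scale simulations and fixtures, not
for hundred-gigabase production runs.
"""

from __future__ import annotations

import gzip
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "KmerSpectrum",
    "SurveyEstimate",
    "QcReport",
    "SurveyResult",
    "read_sequences",
    "q30_fraction",
    "gc_content",
    "count_kmers",
    "filter_error_kmers",
    "find_peak_depth",
    "estimate_genome_size",
    "estimate_heterozygosity",
    "estimate_duplication_ratio",
    "survey_report",
    "write_spectrum_tsv",
    "write_survey_tsv",
]


class KmerError(ValueError):
    """Invalid k-mer analysis input or unusable spectrum."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class KmerSpectrum:
    """Depth → number of distinct (canonical) k-mers at that depth."""

    k: int
    counts: dict[int, int]
    n_windows: int  # k-mer occurrences counted (pre-filter mass)
    error_cutoff: int = 1

    @property
    def total_kmers_retained(self) -> int:
        """Σ depth·count over retained depths (k-mer occurrence mass)."""
        return sum(d * c for d, c in self.counts.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.counts.values())

    def dense_counts(self) -> np.ndarray:
        """Counts as an array indexed by depth (0 .. max depth)."""
        if not self.counts:
            return np.zeros(1, dtype=np.int64)
        arr = np.zeros(max(self.counts) + 1, dtype=np.int64)
        for d, c in self.counts.items():
            arr[d] = c
        return arr


@dataclass
class HetEstimate:
    het_pct: float
    het_mass_fraction: float
    detected: bool


@dataclass
class SurveyEstimate:
    """Headline survey numbers derived from one spectrum."""

    peak_depth: float
    genome_size_bp: float
    genome_size_mb: float
    heterozygosity_pct: float
    duplication_pct: float
    het_detected: bool


@dataclass
class QcReport:
    base_count: int
    q30_pct: float | None  # None when the input carries no qualities
    gc_pct: float


@dataclass
class SurveyResult:
    qc: QcReport
    spectrum: KmerSpectrum  # filtered
    raw_spectrum: KmerSpectrum
    estimate: SurveyEstimate


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    ext = suffixes[-1] if suffixes else ""
    if ext in (".fq", ".fastq"):
        return "fastq"
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    raise KmerError(f"cannot infer format of {path}; pass fmt explicitly")


def read_sequences(path: str | Path, fmt: str | None = None
                   ) -> Iterator[tuple[str, np.ndarray | None]]:
    """Stream (sequence, qualities) records from FASTQ/FASTA (+gzip).

    Qualities are Phred scores as an int array for FASTQ, None for FASTA.
    The whole file is never materialized. A malformed record aborts with
    its index in the error message.
    """
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    if fmt not in ("fastq", "fasta"):
        raise KmerError(f"unsupported format {fmt!r}")
    with _open_maybe_gzip(path) as handle:
        parser = SeqIO.parse(handle, fmt)
        i = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise KmerError(f"{path}: malformed record #{i}: {exc}") from exc
            quals = rec.letter_annotations.get("phred_quality")
            yield str(rec.seq), (np.asarray(quals, dtype=np.int16) if quals is not None else None)
            i += 1


def _as_records(reads) -> Iterable[tuple[str, np.ndarray | None]]:
    """Accept a path, an iterable of (seq, quals), or of bare strings."""
    if isinstance(reads, (str, Path)):
        return read_sequences(reads)
    def gen():
        for r in reads:
            if isinstance(r, str):
                yield r, None
            else:
                yield r[0], r[1]
    return gen()


# ---------------------------------------------------------------------------
# read-level QC
# ---------------------------------------------------------------------------

def q30_fraction(reads) -> float:
    """Percent of sequenced bases with Phred quality ≥ 30."""
    total = hi = 0
    for seq, quals in _as_records(reads):
        if quals is None:
            raise KmerError("q30_fraction needs FASTQ qualities")
        total += quals.size
        hi += int((quals >= 30).sum())
    if total == 0:
        raise KmerError("no bases")
    return 100.0 * hi / total


def gc_content(reads) -> float:
    """Percent G+C over unambiguous (ACGT) bases."""
    gc = at = 0
    for seq, _ in _as_records(reads):
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise KmerError("no unambiguous bases")
    return 100.0 * gc / (gc + at)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _chunk_strings(seqs: Iterable[str], chunk_bases: int) -> Iterator[np.ndarray]:
    """Join reads (separated by 'N') into base-code chunks; reads are
    never split across chunks, so no window is lost or invented."""
    buf: list[str] = []
    size = 0
    for seq in seqs:
        buf.append(seq)
        size += len(seq) + 1
        if size >= chunk_bases:
            yield _CODE[np.frombuffer("N".join(buf).encode("ascii"), dtype=np.uint8)]
            buf, size = [], 0
    if buf:
        yield _CODE[np.frombuffer("N".join(buf).encode("ascii"), dtype=np.uint8)]


def _canonical_window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit codes of all valid k-windows, canonicalized against the
    reverse complement (lexicographic minimum)."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    ok = (cs[k:] - cs[:-k]) == 0
    if not ok.any():
        return np.empty(0, dtype=np.uint64)
    b = codes.astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | b[j:j + m]
        rev = rev | (((three - b[j:j + m]) & three) << np.uint64(2 * j))
    return np.minimum(fwd[ok], rev[ok])


def count_kmers(reads, k: int = 19, canonical: bool = True,
                chunk_bases: int = 8_000_000) -> KmerSpectrum:
    """Exact canonical k-mer counting → depth spectrum.

    ``reads`` may be a FASTQ/FASTA path, an iterable of sequences, or of
    (sequence, qualities) tuples. K-mers spanning non-ACGT symbols are
    skipped. With ``canonical`` each k-mer is identified with its
    reverse complement (lexicographic minimum of the two 2-bit codes);
    k must be odd so no k-mer is its own reverse complement.
    """
    if k % 2 == 0:
        raise KmerError("k must be odd (even k makes canonicalization ambiguous)")
    if not 3 <= k <= 31:
        raise KmerError("k must be in [3, 31]")
    pieces: list[np.ndarray] = []
    seqs = (seq for seq, _ in _as_records(reads))
    for chunk in _chunk_strings(seqs, chunk_bases):
        if canonical:
            w = _canonical_window_codes(chunk, k)
        else:
            w = _forward_window_codes(chunk, k)
        if w.size:
            pieces.append(w)
    if not pieces:
        raise KmerError("no valid k-mer windows in input")
    codes = np.concatenate(pieces)
    n_windows = int(codes.size)
    _, multiplicities = np.unique(codes, return_counts=True)
    depths, ncounts = np.unique(multiplicities, return_counts=True)
    counts = {int(d): int(c) for d, c in zip(depths, ncounts)}
    return KmerSpectrum(k=k, counts=counts, n_windows=n_windows, error_cutoff=1)


def _forward_window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    ok = (cs[k:] - cs[:-k]) == 0
    b = codes.astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | b[j:j + m]
    return fwd[ok]


# ---------------------------------------------------------------------------
# spectrum → estimates
# ---------------------------------------------------------------------------

def filter_error_kmers(spectrum: KmerSpectrum, min_depth: int = 5) -> KmerSpectrum:
    """Drop the error tail: depths below ``min_depth`` are removed."""
    kept = {d: c for d, c in spectrum.counts.items() if d >= min_depth}
    if not kept:
        raise KmerError(
            f"filtering at depth {min_depth} removes the whole spectrum; "
            "coverage is too low for a survey"
        )
    return KmerSpectrum(k=spectrum.k, counts=kept, n_windows=spectrum.n_windows,
                        error_cutoff=min_depth)


def _local_maxima(arr: np.ndarray, lo: int) -> list[int]:
    out = []
    for i in range(max(lo, 1), arr.size - 1):
        if arr[i] > arr[i - 1] and arr[i] >= arr[i + 1] and arr[i] > 0:
            out.append(i)
    return out


def find_peak_depth(spectrum: KmerSpectrum, diploid_aware: bool = False) -> float:
    """Depth of the homozygous-coverage peak, parabolic-refined.

    The global mode of the retained spectrum is located and refined by
    parabolic interpolation over the three bins around it, so the
    returned depth need not be an integer. When a secondary mode near
    half the chosen depth is present (a diploid heterozygous shoulder)
    a warning is emitted; with ``diploid_aware`` the rule inverts: if
    the global mode itself sits near half of a higher-depth mode, the
    higher-depth (homozygous) mode is chosen.
    """
    dense = spectrum.dense_counts()
    lo = spectrum.error_cutoff
    if dense.size <= lo:
        raise KmerError("empty retained spectrum")
    mode = int(lo + np.argmax(dense[lo:]))
    if mode == lo:
        tail = dense[lo:]
        if np.all(np.diff(tail.astype(np.int64)) <= 0):
            raise KmerError(
                "spectrum is monotonically decreasing above the error cutoff "
                "(no interior coverage mode); sequence deeper"
            )
    maxima = _local_maxima(dense, lo)
    if diploid_aware:
        for cand in sorted(maxima, key=lambda i: -dense[i]):
            if abs(cand - 2 * mode) <= max(2, 0.25 * 2 * mode) and \
                    dense[cand] >= 0.2 * dense[mode] and cand > mode:
                logger.info("diploid-aware: homozygous peak %d chosen over %d", cand, mode)
                mode = cand
                break
    else:
        for cand in maxima:
            if cand < mode and abs(cand - mode / 2) <= max(2, 0.25 * mode / 2) and \
                    dense[cand] >= 0.1 * dense[mode]:
                logger.warning(
                    "half-depth shoulder at %d next to peak %d: looks diploid; "
                    "consider diploid_aware=True", cand, mode)
                break
    c0 = float(dense[mode - 1]) if mode - 1 >= 0 else 0.0
    c1 = float(dense[mode])
    c2 = float(dense[mode + 1]) if mode + 1 < dense.size else 0.0
    denom = c0 - 2 * c1 + c2
    if denom >= 0:  # flat or pathological: keep the integer mode
        return float(mode)
    return float(mode + 0.5 * (c0 - c2) / denom)


def estimate_genome_size(spectrum: KmerSpectrum, peak_depth: float) -> tuple[float, float]:
    """(bases, Mb): total retained k-mer count divided by the peak depth."""
    if peak_depth <= 0:
        raise KmerError("peak depth must be positive")
    bp = spectrum.total_kmers_retained / peak_depth
    return bp, bp / 1e6


def estimate_heterozygosity(spectrum: KmerSpectrum, peak_depth: float,
                            k: int | None = None) -> HetEstimate:
    """Per-base heterozygosity from the half-depth spectrum component.

    A two-Gaussian model with means pinned at peak/2 (heterozygous) and
    peak (homozygous) is least-squares fitted to the retained counts on
    [peak/4, 1.6·peak]. The amplitudes are free; the widths are linked
    Poisson-style (σ_het = σ_hom/√2), which keeps the overlapping
    components from trading mass. The
    heterozygous mass fraction b (of the total retained mass) converts
    to a per-base rate via h = 1 − (1 − b)^(1/k). When no half-depth
    component is detectable the estimate is 0 with ``detected=False``.
    """
    k = k or spectrum.k
    d = peak_depth
    dense = spectrum.dense_counts().astype(float)
    lo = max(spectrum.error_cutoff, int(round(0.25 * d)))
    hi = int(round(1.6 * d))
    if hi >= dense.size:
        dense = np.concatenate([dense, np.zeros(hi - dense.size + 1)])
    if hi <= lo + 3:
        return HetEstimate(0.0, 0.0, False)
    x = np.arange(lo, hi + 1, dtype=float)
    y = dense[lo:hi + 1]

    def model(xx, a1, a2, s):
        return (a1 * np.exp(-0.5 * ((xx - d / 2) / (s / math.sqrt(2))) ** 2)
                + a2 * np.exp(-0.5 * ((xx - d) / s) ** 2))

    a1_0 = float(dense[int(round(d / 2))]) if int(round(d / 2)) >= lo else 0.0
    a2_0 = float(dense[int(round(d))])
    p0 = [max(a1_0, 1.0), max(a2_0, 1.0), math.sqrt(max(d, 1.0))]
    try:
        popt, _ = curve_fit(
            model, x, y, p0=p0,
            bounds=([0.0, 0.0, 0.3], [np.inf, np.inf, d]),
            maxfev=20_000,
        )
    except Exception:
        return HetEstimate(0.0, 0.0, False)
    a1, s1 = popt[0], popt[2] / math.sqrt(2)
    het_mass = (d / 2) * a1 * s1 * math.sqrt(2 * math.pi)
    total = spectrum.total_kmers_retained
    b = min(het_mass / total, 0.999999)
    if b < 5e-3:
        return HetEstimate(0.0, float(b), False)
    h = 1.0 - (1.0 - b) ** (1.0 / k)
    return HetEstimate(100.0 * h, float(b), True)


def estimate_duplication_ratio(spectrum: KmerSpectrum, peak_depth: float,
                               repeat_factor: float = 1.8) -> float:
    """Percent of retained k-mer mass at depth > repeat_factor × peak."""
    cut = repeat_factor * peak_depth
    repeat_mass = sum(d * c for d, c in spectrum.counts.items() if d > cut)
    total = spectrum.total_kmers_retained
    return 100.0 * repeat_mass / total


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def survey_report(reads, k: int = 19, min_depth: int = 5,
                  diploid_aware: bool = False,
                  repeat_factor: float = 1.8) -> SurveyResult:
    """QC → count → filter → peak → size/heterozygosity/duplication.

    ``reads`` may be a FASTQ/FASTA path or an in-memory read collection
    (a list is required rather than a one-shot iterator, since the data
    are traversed twice: QC and counting).
    """
    if isinstance(reads, (str, Path)):
        records = list(read_sequences(reads))
    else:
        records = [(r, None) if isinstance(r, str) else (r[0], r[1]) for r in reads]
    have_quals = records and records[0][1] is not None
    qc = QcReport(
        base_count=sum(len(s) for s, _ in records),
        q30_pct=q30_fraction(records) if have_quals else None,
        gc_pct=gc_content(records),
    )
    if not have_quals:
        logger.warning("input carries no base qualities; Q30 unavailable")
    raw = count_kmers(records, k=k)
    filtered = filter_error_kmers(raw, min_depth=min_depth)
    peak = find_peak_depth(filtered, diploid_aware=diploid_aware)
    bp, mb = estimate_genome_size(filtered, peak)
    het = estimate_heterozygosity(filtered, peak, k)
    dup = estimate_duplication_ratio(filtered, peak, repeat_factor)
    est = SurveyEstimate(
        peak_depth=peak,
        genome_size_bp=bp,
        genome_size_mb=mb,
        heterozygosity_pct=het.het_pct,
        duplication_pct=dup,
        het_detected=het.detected,
    )
    return SurveyResult(qc=qc, spectrum=filtered, raw_spectrum=raw, estimate=est)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_spectrum_tsv(spectrum: KmerSpectrum, path: str | Path) -> None:
    """Two-column spectrum plus the normalized per-depth ratio
    (distinct k-mers at depth / all distinct k-mers)."""
    depths = sorted(spectrum.counts)
    total = spectrum.n_distinct
    pd.DataFrame(
        {
            "depth": depths,
            "distinct_kmers": [spectrum.counts[d] for d in depths],
            "ratio": [spectrum.counts[d] / total for d in depths],
        }
    ).to_csv(path, sep="\t", index=False)


def write_survey_tsv(result: SurveyResult, sample: str, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample": sample,
                "kmer_number": result.spectrum.total_kmers_retained,
                "kmer_depth": result.estimate.peak_depth,
                "genome_size_mb": result.estimate.genome_size_mb,
                "heterozygosity_pct": result.estimate.heterozygosity_pct,
                "duplication_pct": result.estimate.duplication_pct,
            }
        ]
    ).to_csv(path, sep="\t", index=False)


def qc_to_json(qc: QcReport) -> str:
    return json.dumps(
        {"base_count": qc.base_count, "q30_pct": qc.q30_pct, "gc_pct": qc.gc_pct},
        indent=2,
    )
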