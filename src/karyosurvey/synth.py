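"""Synthetic inputs with the statistical structure each analysis assumes.

Three generators emulate the three data types of the study design:

* karyotype arm-measurement tables — true per-pair arm lengths observed
  in several metaphase cells with multiplicative Gaussian measurement
  noise;
* flow-cytometry event lists — Gaussian G1 peaks for sample and internal
  reference with a controlled coefficient of variation, an optional G2
  population at twice the G1 mean, and uniform low-channel debris;
* diploid genomes and short reads — an i.i.d. background at a chosen GC
  fraction carrying one exact multi-copy repeat family, a second
  haplotype derived by SNPs at a chosen per-base rate, and uniformly
  placed substitution-error reads with a two-point Phred quality model.

Every generator is deterministic under its spec's seed and returns a
``truth`` dict holding the parameters a recovery test needs, so tests
never re-derive ground truth. The corresponding CLI writes it as
``truth.json`` next to the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .fcm import EventSet
from .karyotype import ArmMeasurement

__all__ = [
    "KaryotypeSpec",
    "FcmSimSpec",
    "GenomeSimSpec",
    "ReadSimSpec",
    "gen_karyotype_measurements",
    "gen_fcm_events",
    "gen_diploid_genome",
    "gen_reads",
    "write_fasta",
    "write_fastq",
    "write_measurements_tsv",
    "write_events_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimSpecError(ValueError):
    """Out-of-range simulation parameters."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class KaryotypeSpec:
    """Arm-measurement simulation: 5 cells with 2% noise by default,
    matching routine metaphase measurement practice."""

    pairs: list[tuple[float, float]]  # (true_short_um, true_long_um)
    noise_cv: float = 0.02
    n_cells: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise SimSpecError("at least one pair required")
        for s, l in self.pairs:
            if s <= 0 or l < s:
                raise SimSpecError(f"invalid true arms ({s}, {l})")
        if not 0 <= self.noise_cv <= 0.2:
            raise SimSpecError("noise_cv outside [0, 0.2]")
        if self.n_cells < 1:
            raise SimSpecError("n_cells must be ≥ 1")


@dataclass
class FcmSimSpec:
    """FCM acquisition simulation. Defaults mirror the acquisition gates
    of the ratio method: ≥10,000 nuclei and a 3% peak CV, with the
    tomato internal reference near channel 2668."""

    ref_mean: float = 2668.08
    ratio: float = 2.3656
    cv_pct: float = 3.0
    n_events: int = 10_000
    g2_fraction: float = 0.10
    debris_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ref_mean <= 0 or self.ratio <= 0:
            raise SimSpecError("ref_mean and ratio must be positive")
        if not 0 <= self.g2_fraction < 0.5 or not 0 <= self.debris_fraction < 0.5:
            raise SimSpecError("g2/debris fractions must lie in [0, 0.5)")
        if self.cv_pct < 0:
            raise SimSpecError("cv_pct must be ≥ 0")
        if self.n_events < 1:
            raise SimSpecError("n_events must be ≥ 1")


@dataclass
class GenomeSimSpec:
    """Diploid genome simulation: SNP-only heterozygosity between two
    haplotypes, one exact multi-copy repeat family, i.i.d. background
    at ``gc_frac`` (default: the ~32% GC typical of spider genomes)."""

    genome_bp: int = 500_000
    gc_frac: float = 0.3245
    heterozygosity: float = 0.0
    repeat_fraction: float = 0.0
    repeat_copies: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_bp < 190:  # ≥ 10·k at the default k = 19
            raise SimSpecError("genome too short")
        for name in ("gc_frac", "heterozygosity", "repeat_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise SimSpecError(f"{name} outside [0, 1)")
        if self.repeat_copies < 2:
            raise SimSpecError("repeat_copies must be ≥ 2")


@dataclass
class ReadSimSpec:
    """Short-read simulation: 150 bp reads (survey-library insert size),
    substitution-only errors, and a two-point quality model whose
    default weight reproduces a ~95% Q30 run."""

    coverage: float = 40.0
    read_len: int = 150
    error_rate: float = 0.005
    q_hi: int = 40
    q_lo: int = 20
    q_hi_weight: float = 0.954
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise SimSpecError("coverage must be positive")
        if self.read_len < 1:
            raise SimSpecError("read_len must be ≥ 1")
        if not 0 <= self.error_rate <= 0.05:
            raise SimSpecError("error_rate outside [0, 0.05]")
        if not 0 <= self.q_hi_weight <= 1:
            raise SimSpecError("q_hi_weight outside [0, 1]")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_karyotype_measurements(spec: KaryotypeSpec
                               ) -> tuple[list[ArmMeasurement], dict]:
    """Noisy per-cell arm measurements around the spec's true arms.

    Arms are drawn as true·(1 + N(0, noise_cv)); a draw that inverts the
    short/long order is swapped back (as an analyst would on ingest).
    """
    rng = np.random.default_rng(spec.seed)
    out: list[ArmMeasurement] = []
    for cell in range(1, spec.n_cells + 1):
        for pid, (s_true, l_true) in enumerate(spec.pairs, start=1):
            s = s_true * (1.0 + rng.normal(0.0, spec.noise_cv)) if spec.noise_cv else s_true
            l = l_true * (1.0 + rng.normal(0.0, spec.noise_cv)) if spec.noise_cv else l_true
            s = max(s, 1e-9)
            l = max(l, 1e-9)
            if s > l:
                s, l = l, s
            out.append(ArmMeasurement(f"cell{cell}", pid, s, l))
    truth = {
        "pairs": [list(p) for p in spec.pairs],
        "noise_cv": spec.noise_cv,
        "n_cells": spec.n_cells,
        "seed": spec.seed,
    }
    return out, truth


def gen_fcm_events(spec: FcmSimSpec) -> tuple[EventSet, EventSet, dict]:
    """(sample, reference) event sets with Gaussian G1/G2 peaks and debris.

    G1 means are ``ratio·ref_mean`` (sample) and ``ref_mean`` (reference);
    G2 events sit at twice the respective G1 mean with the same CV;
    debris is uniform on (0, 0.3·G1 mean).
    """
    rng = np.random.default_rng(spec.seed)

    def one(mean: float, label: str) -> EventSet:
        n = spec.n_events
        n_g2 = int(round(spec.g2_fraction * n))
        n_debris = int(round(spec.debris_fraction * n))
        n_g1 = n - n_g2 - n_debris
        sd = spec.cv_pct / 100.0
        parts = [rng.normal(mean, sd * mean, n_g1)]
        if n_g2:
            parts.append(rng.normal(2 * mean, sd * 2 * mean, n_g2))
        if n_debris:
            parts.append(rng.uniform(1e-6, 0.3 * mean, n_debris))
        x = np.concatenate(parts)
        x = np.clip(x, 1e-6, None)
        rng.shuffle(x)
        return EventSet(label=label, intensities=x)

    sample = one(spec.ratio * spec.ref_mean, "sample")
    reference = one(spec.ref_mean, "reference")
    truth = asdict(spec)
    truth["sample_mean"] = spec.ratio * spec.ref_mean
    truth["expected_size_mb_at_0p85pg"] = spec.ratio * 0.85 * 978.0
    return sample, reference, truth


def _random_bases(rng: np.random.Generator, n: int, gc_frac: float) -> np.ndarray:
    p = np.array([(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def gen_diploid_genome(spec: GenomeSimSpec) -> tuple[str, str, dict]:
    """Two haplotype sequences plus ground truth.

    Haplotype A is i.i.d. background at ``gc_frac`` with one repeat
    family: ``repeat_copies`` exact copies of a random unit, together
    occupying ``repeat_fraction`` of the length, interleaved evenly with
    the background. Haplotype B is a copy of A with SNPs at rate
    ``heterozygosity`` (uniform positions, random alternative base).
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.genome_bp
    unit_len = int(round(spec.repeat_fraction * G / spec.repeat_copies))
    if spec.repeat_fraction > 0 and unit_len < 1:
        raise SimSpecError(
            f"repeat_fraction {spec.repeat_fraction} of {G} bp cannot fit "
            f"{spec.repeat_copies} copies of a non-empty unit"
        )
    n_bg = G - unit_len * spec.repeat_copies
    if n_bg < 0:
        raise SimSpecError("repeat family longer than the genome")
    background = _random_bases(rng, n_bg, spec.gc_frac)
    if unit_len:
        unit = _random_bases(rng, unit_len, spec.gc_frac)
        segments = []
        cuts = np.linspace(0, n_bg, spec.repeat_copies + 1).astype(int)
        for i in range(spec.repeat_copies):
            segments.append(background[cuts[i]:cuts[i + 1]])
            segments.append(unit)
        hap_a = np.concatenate(segments)
    else:
        hap_a = background
    hap_b = hap_a.copy()
    n_snp = rng.binomial(hap_a.size, spec.heterozygosity) if spec.heterozygosity else 0
    if n_snp:
        pos = rng.choice(hap_a.size, size=n_snp, replace=False)
        hap_b[pos] = (hap_b[pos] + rng.integers(1, 4, size=n_snp).astype(np.uint8)) % 4
    realized_rf = unit_len * spec.repeat_copies / hap_a.size
    truth = asdict(spec)
    truth.update(
        {
            "haploid_bp": int(hap_a.size),
            "n_snp": int(n_snp),
            "realized_heterozygosity": n_snp / hap_a.size,
            "realized_gc_frac": float(np.isin(hap_a, (1, 2)).mean()),
            "repeat_unit_bp": unit_len,
            "realized_repeat_fraction": realized_rf,
            # occupancy mass of the repeat family among k-mer occurrences
            "duplication_mass": realized_rf,
            # excess-copy share, for reference
            "excess_repeat_mass": realized_rf * (spec.repeat_copies - 1) / spec.repeat_copies,
        }
    )
    return _codes_to_str(hap_a), _codes_to_str(hap_b), truth


def gen_reads(haplotypes: Sequence[str], spec: ReadSimSpec
              ) -> tuple[list[tuple[str, np.ndarray]], dict]:
    """Uniform substitution-error reads over the haplotypes.

    Total bases ≈ coverage × haploid length, split evenly across the
    haplotypes (half coverage each for a diploid). Returns a list of
    (sequence, Phred-quality array) records.
    """
    G = len(haplotypes[0])
    if spec.read_len > min(len(h) for h in haplotypes):
        raise SimSpecError("read_len exceeds a haplotype length")
    rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.coverage * G / spec.read_len))
    per_hap = [n_total // len(haplotypes)] * len(haplotypes)
    for i in range(n_total - sum(per_hap)):
        per_hap[i] += 1
    reads: list[tuple[str, np.ndarray]] = []
    for hap, n_reads in zip(haplotypes, per_hap):
        if n_reads == 0:
            continue
        codes = _CODE_FROM_STR[np.frombuffer(hap.encode("ascii"), dtype=np.uint8)]
        starts = rng.integers(0, len(hap) - spec.read_len + 1, size=n_reads)
        mat = codes[starts[:, None] + np.arange(spec.read_len)]
        if spec.error_rate:
            err = rng.random(mat.shape) < spec.error_rate
            shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat = np.where(err, (mat + shift) % 4, mat)
        quals = np.where(
            rng.random(mat.shape) < spec.q_hi_weight, spec.q_hi, spec.q_lo
        ).astype(np.int16)
        seq_bytes = _BASES[mat]
        for row, qrow in zip(seq_bytes, quals):
            reads.append((row.tobytes().decode("ascii"), qrow))
    expected_q30 = 100.0 * (
        (spec.q_hi_weight if spec.q_hi >= 30 else 0.0)
        + ((1 - spec.q_hi_weight) if spec.q_lo >= 30 else 0.0)
    )
    truth = asdict(spec)
    truth.update(
        {
            "haploid_bp": G,
            "n_reads": len(reads),
            "total_bases": len(reads) * spec.read_len,
            "expected_q30_pct": expected_q30,
        }
    )
    return reads, truth


_CODE_FROM_STR = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_FROM_STR[ord(_b)] = _i


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(reads: Sequence[tuple[str, np.ndarray]], path: str | Path,
                prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, (seq, quals) in enumerate(reads):
            q = (np.asarray(quals, dtype=np.int16) + 33).astype(np.uint8).tobytes().decode("ascii")
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{q}\n")


def write_measurements_tsv(measurements: Sequence[ArmMeasurement],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tpair_id\tshort_um\tlong_um\n")
        for m in measurements:
            fh.write(f"{m.cell_id}\t{m.pair_id}\t{m.short_um:.6f}\t{m.long_um:.6f}\n")


def write_events_tsv(events: EventSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("intensity\n")
        for v in events.intensities:
            fh.write(f"{v:.6f}\n")
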