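"""Karyotype statistics and classification from chromosome arm measurements.

Implements the standard desk pipeline of comparative cytogenetics: per-pair
arm means over several metaphase cells, relative lengths, arm ratios with
Levan centromere classes, the karyotype formula, the asymmetry coefficient
As.K%, Stebbins asymmetry typing, and the chromosome arithmetic of
multiple-X/0 sex-chromosome systems (XO, X1X2O, X1X2X3O) as found in
spiders and other arachnids.

All lengths are in micrometres (µm). Measurements arrive already paired:
``pair_id`` is assigned upstream by the analyst (karyotyping software);
no automatic homolog matching is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ArmMeasurement",
    "KaryotypePair",
    "KaryotypeInput",
    "KaryotypeSummary",
    "MeioticConfig",
    "LEVAN_BOUNDS",
    "CENTROMERE_CLASSES",
    "load_measurements",
    "aggregate_pairs",
    "relative_length",
    "arm_ratio",
    "classify_centromere",
    "karyotype_formula",
    "asymmetry_coefficient",
    "stebbins_type",
    "scs_arithmetic",
    "summarize_karyotype",
    "idiogram_data",
    "write_summary_tsv",
    "write_per_pair_tsv",
]

#: Levan centromere classes in order of increasing arm ratio.
CENTROMERE_CLASSES = ("m", "sm", "st", "t")

#: Left-closed arm-ratio intervals of the Levan convention:
#: m [1.0, 1.7), sm [1.7, 3.0), st [3.0, 7.0), t [7.0, inf).
LEVAN_BOUNDS = (1.7, 3.0, 7.0)

#: X-chromosome count per sex-chromosome system (male univalents).
SCS_X_COUNT = {"XO": 1, "X1X2O": 2, "X1X2X3O": 3}


class KaryotypeError(ValueError):
    """Invalid karyotype input (gaps, non-positive lengths, parity...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmMeasurement:
    """One chromosome's short/long arm lengths in one metaphase cell."""

    cell_id: str
    pair_id: int
    short_um: float
    long_um: float

    def __post_init__(self) -> None:
        if self.short_um <= 0 or self.long_um <= 0:
            raise KaryotypeError(
                f"non-positive arm length for pair {self.pair_id} "
                f"in cell {self.cell_id!r}: ({self.short_um}, {self.long_um})"
            )
        if self.long_um < self.short_um:
            raise KaryotypeError(
                f"long arm shorter than short arm for pair {self.pair_id}; "
                "swap on ingest (load_measurements does this automatically)"
            )


@dataclass(frozen=True)
class KaryotypePair:
    """Mean arm lengths of one chromosome pair, averaged over cells."""

    pair_id: int
    mean_short_um: float
    mean_long_um: float

    def __post_init__(self) -> None:
        if self.mean_short_um <= 0 or self.mean_long_um < self.mean_short_um:
            raise KaryotypeError(
                f"invalid mean arms for pair {self.pair_id}: "
                f"({self.mean_short_um}, {self.mean_long_um})"
            )

    @property
    def total_um(self) -> float:
        return self.mean_short_um + self.mean_long_um


@dataclass
class KaryotypeInput:
    """A full measured karyotype plus its sex-chromosome bookkeeping.

    ``unpaired_sex_chromosomes`` is 0 for females and equals the number of
    X univalents for males (2 under X1X2O). The diploid number is
    2·len(pairs) + unpaired_sex_chromosomes.
    """

    species: str
    sex: str  # "female" | "male"
    scs: str  # "XO" | "X1X2O" | "X1X2X3O"
    pairs: list[KaryotypePair]
    unpaired_sex_chromosomes: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise KaryotypeError(f"sex must be female/male, got {self.sex!r}")
        if self.scs not in SCS_X_COUNT:
            raise KaryotypeError(f"unknown sex-chromosome system {self.scs!r}")
        if self.sex == "female" and self.unpaired_sex_chromosomes != 0:
            raise KaryotypeError("females carry no unpaired sex chromosomes")
        if self.sex == "male" and self.unpaired_sex_chromosomes != SCS_X_COUNT[self.scs]:
            raise KaryotypeError(
                f"{self.scs} males carry {SCS_X_COUNT[self.scs]} X univalents, "
                f"got {self.unpaired_sex_chromosomes}"
            )

    @property
    def two_n(self) -> int:
        return 2 * len(self.pairs) + self.unpaired_sex_chromosomes


@dataclass
class KaryotypeSummary:
    """Whole-karyotype characters: the usual published table row."""

    species: str
    sex: str
    two_n: int
    rl_pct: list[float]
    ar: list[float]
    centromere_class: list[str]
    kf: str
    cl_range_um: tuple[float, float]
    ml_um: float
    mar: float
    ls: float
    ask_pct: float
    prop_ar_gt2: float
    stebbins: str


@dataclass(frozen=True)
class MeioticConfig:
    """Expected male diakinesis configuration under a multiple-X system."""

    bivalents: int
    sex_univalents: int
    n_formula: str


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------

def load_measurements(path: str | Path,
                      clamp_telocentric: float | None = None
                      ) -> tuple[list[ArmMeasurement], dict]:
    """Read a TSV/CSV of ``cell_id, pair_id, short_um, long_um``.

    Arm pairs with short > long are swapped (with a warning); rows with a
    non-positive length are rejected and counted. A short arm of zero
    (a telocentric measured as armless, for which AR is undefined) is by
    default rejected too; passing ``clamp_telocentric`` (µm) remaps it to
    that minimum instead, which lands the pair in the t class. Returns
    the measurements and an ingest report
    ``{"n_rows", "n_rejected", "n_swapped", "n_clamped"}``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"cell_id", "pair_id", "short_um", "long_um"}
    missing = required - set(df.columns)
    if missing:
        raise KaryotypeError(f"{path}: missing columns {sorted(missing)}")

    out: list[ArmMeasurement] = []
    n_rejected = n_swapped = n_clamped = 0
    for row in df.itertuples(index=False):
        short, long_ = float(row.short_um), float(row.long_um)
        if short == 0 and long_ > 0 and clamp_telocentric:
            short = float(clamp_telocentric)
            n_clamped += 1
        if short <= 0 or long_ <= 0:
            n_rejected += 1
            continue
        if short > long_:
            short, long_ = long_, short
            n_swapped += 1
        out.append(ArmMeasurement(str(row.cell_id), int(row.pair_id), short, long_))
    if n_rejected:
        logger.warning("%s: rejected %d rows with non-positive arm lengths", path, n_rejected)
    if n_swapped:
        logger.warning("%s: swapped short/long on %d rows", path, n_swapped)
    if n_clamped:
        logger.warning("%s: clamped %d zero short arms to %g µm (telocentric)",
                       path, n_clamped, clamp_telocentric)
    report = {"n_rows": int(len(df)), "n_rejected": n_rejected,
              "n_swapped": n_swapped, "n_clamped": n_clamped}
    return out, report


def aggregate_pairs(measurements: Sequence[ArmMeasurement]) -> list[KaryotypePair]:
    """Arithmetic mean of arm lengths per pair over all cells and homologs.

    ``pair_id`` values must form a contiguous 1..n set; a gap raises an
    error naming the missing pairs.
    """
    if not measurements:
        raise KaryotypeError("no measurements")
    by_pair: dict[int, list[ArmMeasurement]] = {}
    for m in measurements:
        by_pair.setdefault(m.pair_id, []).append(m)
    n = max(by_pair)
    gaps = sorted(set(range(1, n + 1)) - set(by_pair))
    if gaps or min(by_pair) < 1:
        raise KaryotypeError(f"pair_ids must cover 1..{n}; missing {gaps}")
    pairs = []
    for pid in range(1, n + 1):
        ms = by_pair[pid]
        pairs.append(
            KaryotypePair(
                pair_id=pid,
                mean_short_um=sum(m.short_um for m in ms) / len(ms),
                mean_long_um=sum(m.long_um for m in ms) / len(ms),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# per-pair statistics
# ---------------------------------------------------------------------------

def relative_length(pairs: Sequence[KaryotypePair]) -> list[float]:
    """Per-pair relative length RL_i = 100·(total length of pair i)/(complement length).

    Sums to 100 by construction.
    """
    if not pairs:
        raise KaryotypeError("relative_length of an empty karyotype")
    total = sum(p.total_um for p in pairs)
    return [100.0 * p.total_um / total for p in pairs]


def arm_ratio(pair: KaryotypePair) -> float:
    """Arm ratio AR = long/short ≥ 1; undefined for a zero short arm."""
    if pair.mean_short_um <= 0:
        raise KaryotypeError(
            f"pair {pair.pair_id}: zero/negative short arm — AR undefined; "
            "clamp telocentrics to a minimum short arm before calling"
        )
    return pair.mean_long_um / pair.mean_short_um


def classify_centromere(ar: float) -> str:
    """Levan centromere class from the arm ratio, left-closed intervals.

    m [1.0, 1.7), sm [1.7, 3.0), st [3.0, 7.0), t [7.0, ∞).
    """
    if ar < 1.0:
        raise KaryotypeError(f"arm ratio {ar} < 1 (long arm must be the longer)")
    for cls, hi in zip(CENTROMERE_CLASSES, LEVAN_BOUNDS):
        if ar < hi:
            return cls
    return "t"


def karyotype_formula(
    classes: Sequence[str],
    two_n: int,
    unpaired_sex_chromosomes: int = 0,
    unpaired_classes: Sequence[str] | None = None,
) -> str:
    """Karyotype formula like ``"14m+12sm"``: chromosome counts per class.

    Each pair contributes 2 chromosomes. Male X univalents are included
    only when their classes are supplied (``unpaired_classes``); otherwise
    the formula covers the measured complement and the stated univalent
    count is left outside it. Class order is fixed m, sm, st, t; zero
    terms are omitted; counts must reconcile with ``two_n``.
    """
    if not classes:
        raise KaryotypeError("empty class list")
    bad = set(classes) - set(CENTROMERE_CLASSES)
    if bad:
        raise KaryotypeError(f"unknown centromere classes {sorted(bad)}")
    counts = {c: 0 for c in CENTROMERE_CLASSES}
    for c in classes:
        counts[c] += 2
    covered = 2 * len(classes)
    if unpaired_classes is not None:
        if len(unpaired_classes) != unpaired_sex_chromosomes:
            raise KaryotypeError(
                f"{unpaired_sex_chromosomes} univalents but "
                f"{len(unpaired_classes)} univalent classes"
            )
        for c in unpaired_classes:
            counts[c] += 1
        covered += len(unpaired_classes)
    if covered + (0 if unpaired_classes is not None else unpaired_sex_chromosomes) != two_n:
        raise KaryotypeError(
            f"class counts cover {covered} chromosomes plus "
            f"{unpaired_sex_chromosomes if unpaired_classes is None else 0} stated "
            f"univalents, inconsistent with 2n={two_n}"
        )
    return "+".join(f"{counts[c]}{c}" for c in CENTROMERE_CLASSES if counts[c])


def asymmetry_coefficient(pairs: Sequence[KaryotypePair]) -> float:
    """As.K% = 100·(Σ long arms)/(Σ all arms); 50 for a fully metacentric set."""
    if not pairs:
        raise KaryotypeError("asymmetry_coefficient of an empty karyotype")
    long_sum = sum(p.mean_long_um for p in pairs)
    total = sum(p.total_um for p in pairs)
    return 100.0 * long_sum / total


def stebbins_type(ls: float, prop_ar_gt2: float, classic: bool = False) -> str:
    """Stebbins asymmetry category (one of 12: "1A".."4C").

    The number encodes the proportion of chromosomes with arm ratio > 2
    (1: =0; 2: (0, 0.50]; 3: (0.50, 0.99]; 4: > 0.99) and the letter the
    longest/shortest length ratio (A: < 2; B: [2, 4]; C: > 4). With
    ``classic=True`` the axes swap (number from L/S in 1..3, letter from
    the proportion in A..D) for cross-checking against sources that
    orient the table the other way.
    """
    if ls < 1:
        raise KaryotypeError(f"L/S ratio {ls} < 1")
    if not 0 <= prop_ar_gt2 <= 1:
        raise KaryotypeError(f"proportion {prop_ar_gt2} outside [0, 1]")
    if prop_ar_gt2 == 0:
        prop_cls = 0
    elif prop_ar_gt2 <= 0.50:
        prop_cls = 1
    elif prop_ar_gt2 <= 0.99:
        prop_cls = 2
    else:
        prop_cls = 3
    if ls < 2:
        ls_cls = 0
    elif ls <= 4:
        ls_cls = 1
    else:
        ls_cls = 2
    if classic:
        return f"{ls_cls + 1}{'ABCD'[prop_cls]}"
    return f"{prop_cls + 1}{'ABC'[ls_cls]}"


def scs_arithmetic(male_two_n: int, scs: str) -> tuple[int, MeioticConfig]:
    """Chromosome arithmetic of a multiple-X/0 sex-chromosome system.

    Males carry #X unpaired X chromosomes (univalents at diakinesis);
    females carry each X twice. Hence female 2n = male 2n + #X, and the
    male diakinesis shows (male 2n − #X)/2 autosomal bivalents plus #X
    univalents, e.g. ``n = 11 + X1X2`` for male 2n = 24 under X1X2O.
    """
    if scs not in SCS_X_COUNT:
        raise KaryotypeError(f"unknown sex-chromosome system {scs!r}")
    n_x = SCS_X_COUNT[scs]
    autosomes = male_two_n - n_x
    if autosomes <= 0 or autosomes % 2:
        raise KaryotypeError(
            f"male 2n={male_two_n} under {scs} leaves {autosomes} autosomes, "
            "which is not an even positive count"
        )
    bivalents = autosomes // 2
    xs = "".join(f"X{i + 1}" for i in range(n_x)) if n_x > 1 else "X"
    config = MeioticConfig(
        bivalents=bivalents,
        sex_univalents=n_x,
        n_formula=f"n = {bivalents} + {xs}",
    )
    return male_two_n + n_x, config


# ---------------------------------------------------------------------------
# whole-karyotype summary
# ---------------------------------------------------------------------------

def summarize_karyotype(inp: KaryotypeInput, classic_stebbins: bool = False) -> KaryotypeSummary:
    """All whole-karyotype characters from per-pair means.

    CL range and L/S use per-pair total lengths; ML is their mean; MAR is
    the mean of the per-pair arm ratios (identical to the per-chromosome
    mean, since homologs share the pair mean).
    """
    pairs = inp.pairs
    if not pairs:
        raise KaryotypeError("karyotype with no measured pairs")
    totals = [p.total_um for p in pairs]
    ars = [arm_ratio(p) for p in pairs]
    classes = [classify_centromere(a) for a in ars]
    prop_gt2 = sum(a > 2 for a in ars) / len(ars)
    ls = max(totals) / min(totals)
    return KaryotypeSummary(
        species=inp.species,
        sex=inp.sex,
        two_n=inp.two_n,
        rl_pct=relative_length(pairs),
        ar=ars,
        centromere_class=classes,
        kf=karyotype_formula(classes, inp.two_n, inp.unpaired_sex_chromosomes),
        cl_range_um=(min(totals), max(totals)),
        ml_um=sum(totals) / len(totals),
        mar=sum(ars) / len(ars),
        ls=ls,
        ask_pct=asymmetry_coefficient(pairs),
        prop_ar_gt2=prop_gt2,
        stebbins=stebbins_type(ls, prop_gt2, classic=classic_stebbins),
    )


def idiogram_data(pairs: Sequence[KaryotypePair]) -> pd.DataFrame:
    """Idiogram bar-chart table: long arms as negative extents, short positive."""
    if not pairs:
        raise KaryotypeError("idiogram of an empty karyotype")
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "long_um": [-p.mean_long_um for p in pairs],
            "short_um": [p.mean_short_um for p in pairs],
        }
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_summary_tsv(summary: KaryotypeSummary, path: str | Path) -> None:
    row = {
        "species": summary.species,
        "sex": summary.sex,
        "2n": summary.two_n,
        "CL_min": summary.cl_range_um[0],
        "CL_max": summary.cl_range_um[1],
        "ML": summary.ml_um,
        "MAR": summary.mar,
        "L_S": summary.ls,
        "AsK_pct": summary.ask_pct,
        "prop_AR_gt2": summary.prop_ar_gt2,
        "KT": summary.stebbins,
        "KF": summary.kf,
    }
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)


def write_per_pair_tsv(summary: KaryotypeSummary, pairs: Sequence[KaryotypePair],
                       path: str | Path) -> None:
    pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "short": [p.mean_short_um for p in pairs],
            "long": [p.mean_long_um for p in pairs],
            "total": [p.total_um for p in pairs],
            "RL_pct": summary.rl_pct,
            "AR": summary.ar,
            "class": summary.centromere_class,
        }
    ).to_csv(path, sep="\t", index=False)


def summary_to_json(summary: KaryotypeSummary, pairs: Sequence[KaryotypePair]) -> str:
    """JSON report mirroring the summary and per-pair tables."""
    obj = {
        "summary": {
            "species": summary.species,
            "sex": summary.sex,
            "two_n": summary.two_n,
            "cl_range_um": list(summary.cl_range_um),
            "ml_um": summary.ml_um,
            "mar": summary.mar,
            "ls": summary.ls,
            "ask_pct": summary.ask_pct,
            "prop_ar_gt2": summary.prop_ar_gt2,
            "stebbins": summary.stebbins,
            "kf": summary.kf,
        },
        "pairs": [
            {
                "pair_id": p.pair_id,
                "short_um": p.mean_short_um,
                "long_um": p.mean_long_um,
                "rl_pct": rl,
                "ar": ar,
                "class": cls,
            }
            for p, rl, ar, cls in zip(
                pairs, summary.rl_pct, summary.ar, summary.centromere_class
            )
        ],
    }
    return json.dumps(obj, indent=2)
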