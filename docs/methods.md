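# Methods

This note records the models, estimators, parameter choices, and known
limitations behind the three analysis modules and the synthetic-data
generators.

## Karyotype statistics

Measurements arrive as per-cell, per-pair arm lengths (µm), already paired
by the analyst; the module deliberately does not attempt homolog matching,
since in practice pairing is done in karyotyping software. Ingest swaps a
short/long inversion (with a warning) and rejects non-positive lengths,
counting both in the ingest report. Per-pair means are plain arithmetic
means over all measurements of a pair.

Derived quantities are the standard ones: relative length
RL_i = 100·(S_i+L_i)/Σ(S+L) (which sums to 100 by construction), arm ratio
AR = L/S, the asymmetry coefficient As.K% = 100·ΣL/Σ(S+L) (bounded in
[50, 100]; 50 iff every chromosome is perfectly metacentric), L/S as the
ratio of longest to shortest per-pair total lengths, and MAR as the mean
of per-pair arm ratios. Because homologs share their pair mean, averaging
arm ratios over pairs and over all 2n chromosomes coincide; the
distinction only matters when homologs are kept separate, which this
pipeline does not do.

**Centromere classes.** The Levan-convention cutoffs are not universally
printed with data tables, so they are fixed here explicitly:
m [1.0, 1.7), sm [1.7, 3.0), st [3.0, 7.0), t [7.0, ∞), left-closed. Ties
at a boundary therefore go to the higher class (1.7 → sm, 7.0 → t). A
measured short arm of zero makes AR undefined; the default is to reject
such a record, with an opt-in clamp to a small minimum that classifies
the chromosome as telocentric.

**Stebbins type.** The twelve categories combine the proportion p of
chromosomes with AR > 2 (1: p = 0; 2: 0 < p ≤ 0.50; 3: 0.50 < p ≤ 0.99;
4: p > 0.99) with the L/S class (A: < 2; B: 2–4; C: > 4). Published
spider tables use the orientation number-from-p / letter-from-L/S, which
is what `stebbins_type` returns; a `classic=True` flag swaps the axes for
cross-checking against sources oriented the other way. The interior
category edges (0.50, 0.99) cannot be pinned down from two published data
points per species; the values above are the conventional ones and are
left-closed on the upper edge.

**Karyotype formula.** Chromosome counts per class in fixed order m, sm,
st, t, two per pair, omitting zero terms. Male X univalents enter the
formula only when their measured classes are supplied; otherwise the
formula covers the measured complement and the stated univalent count is
kept outside it (sex chromosomes in these spiders cannot be localized on
mitotic plates, so forcing a class would invent data).

**Sex-chromosome arithmetic.** For an X…O system with x X chromosomes,
female 2n = male 2n + x, male diakinesis shows (male 2n − x)/2 autosomal
bivalents plus x univalents. A male 2n for which (2n − x) is odd or
non-positive is rejected as internally inconsistent.

## Flow-cytometry sizing

The estimator is the ratio method:
2C_sample = (F_sample/F_ref)·2C_ref, genome size = 2C·978 Mb/pg. The
default reference is 2C = 0.85 pg (tomato). Full precision is kept
through the chain; rounding happens only at presentation. This matters:
a 2C printed as 2.01 pg corresponds to 1966.5 Mb, whereas 2.01·978 would
give 1965.8.

**Peak location.** Published tables report a "mean fluorescence
intensity" per peak without specifying gating. The implementation bins
events into 1,024 bins over [0, max], drops debris below 2% of the
maximum channel, smooths with a 5-bin moving average, and ranks local
maxima by event mass. The chosen peak's statistics are mode-anchored:
events within ±25% of the mode give a median re-anchor and a robust
sigma (1.4826·MAD), and the reported mean and CV are computed over events
within ±2σ of that center. The windowed CV of a Gaussian peak is
deflated by the ±2σ truncation (factor ≈ 0.88), uniformly for sample and
reference; the 5% gate is applied to this windowed value. Two candidate
peaks within 10% of each other's mass raise an ambiguity error listing
both; a co-stained acquisition can instead be split explicitly, assigning
the reference to the smaller-mean peak by default.

**QC.** Acquisitions need ≥ 10,000 events and peak CV ≤ 5%; failures are
enumerated, never silently ignored, and abort the pipeline unless forced.
Replicates are combined by the arithmetic mean, with per-replicate values
retained.

Native input is one numeric intensity column in TSV/CSV. FCS containers
are out of scope; exporting a channel to text is assumed upstream.

## K-mer survey

Counting is exact: reads are 2-bit encoded, every window of k consecutive
ACGT bases contributes one occurrence (windows spanning other symbols are
skipped), and each k-mer is identified with the lexicographic minimum of
itself and its reverse complement. k must be odd, which guarantees no
k-mer is its own reverse complement. The spectrum is the histogram of
per-distinct-k-mer multiplicities; by construction Σ depth·count equals
the window count exactly, which the tests assert as an invariant.
Counting holds one uint64 code array in memory and is intended for
survey-simulation scale (up to tens of millions of windows), not for
production hundred-gigabase runs.

**Error filter.** Depths below 5 are discarded; at survey coverages a
specific sequencing-error k-mer is seen ≪ 5 times (expected depth
≈ coverage·error/3), while true k-mers sit near the coverage peak, so the
filter separates the two regimes cleanly at the default 0.5% error rate.

**Peak and size.** The homozygous peak is the global mode of the retained
spectrum, refined by parabolic interpolation over the three bins around
it (hence non-integer depths). A spectrum that only decays above the
cutoff has no interior mode and is rejected with advice to sequence
deeper. When a secondary mode near half the chosen depth exists, a
diploid warning is emitted; in diploid-aware mode the rule inverts and
the higher-depth mode is chosen when the global mode sits near half of
it. Genome size = retained mass / peak depth. The mode of the depth
distribution sits slightly below its mean (Poisson-like skew), which
biases sizes high by ~1%; together with mode-quantization noise this
leaves single-run errors of 0–3% at 500 kb/40×, with the 20-seed median
comfortably under 3%.

**Heterozygosity.** A k-mer overlapping any of k bases of a SNP differs
between haplotypes and appears at half the homozygous depth. With b the
fraction of retained k-mer mass in the half-depth component, the
per-base rate is h = 1 − (1 − b)^(1/k). b is estimated by least-squares
fitting two Gaussians with means pinned at peak/2 and peak to the
retained counts on [peak/4, 1.6·peak]; amplitudes are free and the
widths are linked Poisson-style (σ_het = σ_hom/√2), which stops the
overlapping components from trading mass (free widths underestimated b
by ~15% in validation). If the fitted half-depth mass fraction is below
0.5% or the fit fails, the estimate is 0 with a `detected=False` flag.
The model is validated purely by synthetic recovery (±0.2 percentage
points at true h of 0.4–0.8%); published heterozygosity figures from
survey tools with unpublished internal models are not comparable targets.

**Duplication.** The fraction of retained mass at depth > 1.8× peak
(configurable). For a c-copy exact repeat family all copies sit at
c× peak, so this measures the family's occupancy mass — 20% of the
genome as a two-copy repeat yields ≈ 20%, slightly less in practice
because junction-spanning windows and binomial depth spread leak mass
below the threshold (observed ≈ 3 pp low at 20% repeat mass, within the
±5 pp validation band).

**QC.** Q30 is the percentage of bases with Phred ≥ 30 (FASTQ only); GC
is computed over unambiguous bases only.

## Synthetic generators

The generators emit the statistical structure the estimators assume, plus
a truth sidecar:

- **Arm tables**: arms drawn as true·(1 + N(0, cv)) per cell, cv = 2% by
  default over 5 cells, matching routine measurement practice.
- **FCM events**: G1 Gaussians at the reference mean (default channel
  2668.08) and ratio× it, CV 3% by default; optional G2 at 2× with the
  same CV, debris uniform on (0, 0.3·G1). Defaults n = 10,000 events.
- **Genomes**: i.i.d. background at 32.45% GC (a typical spider value);
  one exact repeat family of `copies` copies interleaved evenly with the
  background; haplotype B is a SNP-mutated copy of A (uniform positions,
  random alternative base). SNP-only heterozygosity keeps the expected
  half-depth mass analytically at 1 − (1−h)^k; exact repeat copies make
  the occupancy mass equal the repeat fraction.
- **Reads**: fixed 150 bp, uniform starts, half the coverage per
  haplotype, substitution-only errors (default 0.5%), and a two-point
  quality model whose default weight (0.954 at Q40/Q20) reproduces a
  ~95% Q30 run.

What the generators do **not** emulate — indels, diverged repeat copies,
GC-coverage bias, instrument-specific error profiles, PCR duplicates,
cell-cycle S-phase continuum, debris with structure — bounds what passing
recovery tests show: they validate the estimators under their own model
assumptions, not robustness to every artifact of real libraries or
acquisitions.

## Problem sizes and numerical choices

Recovery suites use 500 kb haploid genomes at 40× (≈ 18M k-mer windows
per run), 20 seeds for size and 5 per condition for heterozygosity and
duplication, and 50 seeded FCM acquisitions of 10,000 events — sizes at
which every estimator's sampling noise is well below the tolerance being
checked. Histogram binning (1,024 bins), the 2% debris cutoff, the 5-bin
smoother, the 10% peak-ambiguity band, and the 1.8× repeat threshold are
configurable defaults chosen to reproduce Gaussian/Poisson truth on the
generators; none is fitted to data.

## Known limitations

- The FCM windowed CV understates the population CV by the truncation
  factor; gating is consistent because the same window is always used.
- Mode-based peak depth carries a small positive size bias (see above);
  a fitted spectrum model (GenomeScope-style) would remove it but is out
  of scope.
- The heterozygosity mixture assumes a clean diploid with a separable
  half-depth component; at h ≲ 0.1% or coverage ≲ 15× the component
  merges with the homozygous peak and the estimate degrades toward the
  detection flag.
- Duplication mass is a threshold statistic, not a repeat-model fit; it
  undercounts families whose depth spread crosses the threshold.
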