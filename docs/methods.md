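# Methods

## Quantification model

The pipeline starts from gene-level iBAQ tables (rows = gene products,
columns = samples). Undetected gene products are stored as 0, never as a
distinct missing code, and "detected" means value > 0 throughout; no
pseudocounts are added anywhere, because a zero is informative (the
strongest possible depletion evidence when it occurs in a flow-through).
Sample load is removed by iFOT normalization, iFOT(p, s) =
iBAQ(p, s) / Σ_q iBAQ(q, s), which makes every sample a composition
(column sums 1 within 1e-9). Correlation and PCA operate on iFOT values
as-is by default; an optional log10(iFOT + 1e-9) flag exists but is off,
since compositional iFOT is the scale on which replicate agreement is
usually reported for this assay. PCA is centering-only by default
(scaling exposed as a flag) and is computed by SVD of the centered
samples × proteins matrix; component signs are fixed so each score
vector's largest-magnitude entry is positive. Everywhere a z-score or
t-statistic appears, the sample standard deviation (n − 1) is used.

## Enrichment calling

A protein is lysosome-enriched in one condition when three criteria
hold:

1. **Fold over flow-through, per replicate (inclusive ≥ 10).** The
   ratio iFOT_IP / iFOT_FT is formed for each replicate pair in which
   the protein is detected in the IP fraction; FT = 0 with IP > 0 gives
   +inf, which passes.
2. **Repeated in all replicates.** "All" means all replicates in which
   the protein is detected in the IP fraction, with a floor of
   `min_ip_detected = 2`. This reading is forced by the treatment of
   low-abundance V0 subunit VHA-17-type cases: detection in only 2 of 4
   IP replicates, both ≥ 10-fold, still counts as enriched.
3. **Fold over non-tag controls (strict > 2).** Non-tag controls (n = 3)
   do not pair with IP replicates (n = 4), so the comparison uses means
   across replicates: mean IP iFOT > 2 × mean non-tag iFOT. Whether the
   original analysis used means or per-replicate comparisons is not
   documented; means are the only well-defined choice for unpaired
   control counts.

Thresholds are monotone by construction (raising either fold threshold
can only shrink the candidate set), and calling is invariant to
rescaling any raw iBAQ column, since iFOT absorbs per-sample scale. Both
properties are enforced by tests, and the vectorized caller is checked
against a loop-based reimplementation on small random matrices.

## Tissue-heterogeneity groups

Tissue-specific IPs cannot use their flow-through as a depletion control
(it still contains lysosomes from other tissues), so each protein's iFOT
is divided by the bait marker's iFOT in the same replicate, and the
marker-normalized ratios are compared between whole-body and
tissue-specific experiments with an unpaired two-tailed Student's t-test
(equal variance, matching the conventional "Student's t" wording; a
Welch flag exists). Ratios are formed per replicate and averaged
afterwards, not the reverse. Degenerate cases are explicit: both sides
constant and equal → p = 1 (Group I); fewer than two usable replicates
on a side → "untestable", reported as Group I with p = NaN plus a
warning; undetected in every tissue replicate → Group IV regardless of
p. Protein-level aggregation across several tissues is this package's
own policy (the grouping rule behind published single-number group
counts is undocumented): IV only when absent in *all* analyzed tissues;
any significant increase with no significant decrease → II (III
symmetric); increase in one tissue and decrease in another →
"discordant", excluded from the I–III totals; all-untestable →
"untestable"; otherwise I. Shrinking alpha can only move proteins
toward Group I.

## Set comparison and proportions

Overlap percentages are rounded half-away-from-zero; this reproduces the
published derived values 61 (60.80), 57 (56.76), 60 (60.45), 39 (39.20),
18 (17.68), 7 (6.61) and 78.5 from their underlying counts. One
published figure — "82%" for 176/216 = 81.48 — is **not** reproduced by
this rule (it would print 81); the discrepancy is documented here rather
than special-cased. Exclusive-region (upset) decomposition is limited to
six sets to guard the 2^k blow-up. The two-sample test for equality of
proportions is the pooled chi-square on the 2×2 table with df = 1; with
no continuity correction the statistic equals the squared two-sample z
statistic (property-tested), and the Yates-corrected form
(|O − E| − 0.5, floored at 0) is available because the software behind
published p-values of this test is unstated. Annotation sources are
user-supplied mappings; no ontology is bundled, since annotation
databases drift between releases.

## Radial positioning

The cell outline must be convex (unique ray exit); the nucleus outline
need only be simple and strictly inside. "Radiating at all angles" is
implemented exactly per pixel rather than by a finite ray fan: for each
pixel, the ray from the nucleus area centroid through the pixel is
intersected with both polygons, giving the nuclear crossing t_n and cell
exit t_c in units of the pixel's own parameter (t = 1). The fractional
position f = (1 − t_n)/(t_c − t_n) is clamped to [0, 1) and binned into
R half-open shells [i/R, (i+1)/R), so a pixel exactly on the cell
boundary lands in shell R − 1. R defaults to 8, matching the number of
per-region comparisons conventionally plotted for this assay, and is
configurable. All ray geometry uses cross/dot products only (no
trigonometry), which makes shell labels bit-exact under 90° rotations of
the pixel grid; the vectorized assignment is verified pixel-for-pixel
against a scalar edge-enumeration oracle.

Profile normalization divides each shell's mean intensity by the mean
over cytosolic pixels only (nuclear pixels excluded, because the
quantified marker is cytoplasmic; a flag can include them). The
cumulative distribution runs from the innermost shell outward and ends
at 1. Two internal identities hold exactly: the area-weighted mean of
the normalized shell means is 1, and R = 8 profiles aggregate
area-weighted to R = 4 profiles. Groups of cells are compared per shell
with the same Student's t convention as above.

## Synthetic data

The generators define the benchmark conditions; their defaults are fixed
and not tuned per analysis.

**Proteome.** Bulk abundances are log-normal (ln-sd 1.0, a moderate LFQ
dynamic range). Each protein's mass splits between bead and flow-through
by capture odds: truly lysosomal proteins draw odds from a log-normal
with median 50 (ln-sd 0.25), all others share nonspecific background
odds of 0.02. The odds parameterization is what makes the paired design
realistic — enrichment on the bead implies depletion of the same
molecules from the flow-through. Non-tag controls are the bulk
composition plus 5% IP-composition carryover (nonspecific bead binding).
Replicate noise is multiplicative log-normal at CV 0.2, and any value
whose within-sample fraction falls below 1e-6 is zeroed
(abundance-dependent dropout). Defaults: 1000 proteins, 100 lysosomal,
4 IP/FT pairs, 3 non-tag controls. In the noiseless, no-dropout limit
the caller recovers the truth set exactly (tested). The tissue generator
draws true marker-normalized ratios from the same log-normal, applies a
per-protein fold change in the tissue columns (fold 0 = dropped =
truth-IV), and multiplies ln-sd 0.1 replicate noise onto 4 whole-body
vs 3 tissue replicates.

**Cells.** Cell and nucleus outlines are convex hulls of jittered circle
points (so the convexity requirement holds by construction; invalid
draws where the nucleus is not strictly interior are rejected and
redrawn). Puncta get a uniform angle and a fractional radial position f
from a named law — uniform, or Beta(a, b) with a < b perinuclear-biased
and a > b peripheral-biased — then are placed between the nuclear and
cell boundary along that angle and rendered as isotropic Gaussian spots
(sigma 1.5 px, ±4 sigma support) over a constant background, with
optional Poisson noise. Because both polygons are convex, a punctum
center always lies in the cytosol; no rejection loop is needed at
placement. Defaults: 192×192 image, 300 puncta.

What the generators deliberately do **not** model: mass-spectrometer
physics, peptide digestion and protein inference, ratio compression,
correlated (batch) noise between samples, optical PSF structure beyond
an isotropic Gaussian, uneven illumination, and non-convex cells.
Passing the recovery benchmarks therefore demonstrates correctness of
the analysis logic under the stated statistical structure, not
performance on any particular instrument's or microscope's artifacts.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 1000-protein proteomes for
caller benchmarking, ≤ 20×12 matrices for brute-force oracle
equivalence, 500 single-protein simulations for the Group-II recovery
rate, 64×64 geometries for exact pixel-oracle comparison, one
256×256/2000-punctum cell for the uniform-law identity check, and 50 + 50
cells at 192×192 for the Beta-separation comparison. These sizes give
decisive statistics (recovery rates at 100%, separation p-values below
1e-70) in seconds on one CPU. Tolerances: exact equality where the
arithmetic is exact (shell labels, set counts, rotation invariance of
labels), 1e-9–1e-12 for floating-point identities, ±0.05 for
law-of-large-numbers cumulative-profile checks.

## Known limitations

* The published headline candidate counts (216, 449, 259, 177, 200,
  293) depend on the deposited raw MS data and a spectral search; the
  package reproduces the *derived* set arithmetic from those counts and
  benchmarks the caller on synthetic truth instead.
* Group IV cannot distinguish true tissue absence from detection
  dropout; it is an absence-of-evidence class, as in the source assay.
* The radial algorithm requires a convex cell; strongly non-convex cells
  would need a different position parameterization (e.g. geodesic
  distance), which is out of scope.
* The marker-normalization step assumes the bait marker's lysosomal
  abundance is itself comparable across tissues; a tissue that changes
  marker expression rescales all its ratios.
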