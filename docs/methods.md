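# Methods

This note documents the models and procedures implemented in `oiserum`, the
parameters that matter, the numerical choices, what the synthetic generators
emulate, and the known limitations.

## Paired differential expression by per-line voting

The design is a paired cohort of cell lines, each measured under a basal and
a post-treatment condition. The pipeline takes any non-negative gene-level
matrix (counts or FPKM; upstream quantification is out of scope), quantile
normalizes the sample columns (each column's values are replaced by the
cross-sample mean of its ranks' order statistics; tied values receive the
mean of their tied ranks' reference values, which keeps the map
deterministic), and stabilizes variance as log2(x+1).

For gene g and line ℓ, let d_gℓ = post − basal on the transformed scale.
Direction-specific ballots:

* up: d_gℓ > +θ_vote → "for", d_gℓ < −θ_vote → "against";
* down: mirrored; |d_gℓ| ≤ θ_vote abstains.

A gene is selected in a direction iff votes_for ≥ min_votes **and** the
one-tailed paired t-test on {d_gℓ} in that direction gives p < α. Selected
genes are ranked by ascending p (ties broken by gene order).

Parameter defaults: θ_vote = 0.1 log2 units (the dead band below which a
line's change is treated as noise), min_votes = 9 (of a 10-line cohort — a
near-unanimity rule; exposed as a parameter because the appropriate quorum
for other cohort sizes is a design choice, not derivable), α = 0.05.

Numerical/degenerate choices:

* "Tailed" testing is one-tailed in the voted direction: the ballot fixes
  the direction of interest before the test, so a two-sided p would double
  count.
* Zero-variance differences: all-zero gives the symmetric null (t = 0,
  p = 0.5); constant non-zero differences have no defined t and are
  excluded from ranking with p = 1. With continuous data both are
  measure-zero.
* A gene reaching min_votes but failing α keeps its ballot in the output
  with direction "none".
* If min_votes ≤ n/2 a gene could qualify in both directions; the
  better-voted direction wins (tie: smaller p, then up). With the default
  near-unanimity quorum this cannot occur.
* Quantile normalization is exactly idempotent on tie-free data; with
  cross-column ties the tie-averaging step can perturb a column's multiset,
  so idempotence then holds only approximately. Contract tests use
  continuous data.

Companions: highly-variable gene selection (largest cross-sample variance,
ties broken lexicographically by gene id), UPGMA clustering of samples on
Euclidean distances (scipy average linkage; merge heights are the
average inter-cluster distances and are non-decreasing), and centered PCA of
sample columns (SVD; components ordered by variance; each component's sign
fixed so its largest-magnitude loading is positive).

## Trabecular morphometry

Inputs are 2-D grayscale radiograph ROIs with a physical pixel size; the
word "pixel" is used throughout (the inputs are plain radiographs, not CT
volumes). Exclusion of implants or callus is delegated to the user-supplied
mask, mirroring manual ROI practice.

1. **Flat-field correction.** The background is estimated by a Gaussian
   filter of sigma = `kernel_scale` pixels (default: a quarter of the
   smaller ROI dimension, far above any trabecular feature scale) with
   mirror boundary handling, subtracted, and the image re-centered on its
   original mean. Constant images pass through unchanged. No specific
   vendor algorithm is claimed; the contract (gradient removal on phantoms,
   mean preservation) is what is tested.
2. **Otsu binarization.** The threshold maximizes between-class variance
   over the *exact* histogram of observed intensities (each distinct value
   its own bin), then is placed halfway to the next distinct value. The
   exact histogram matters: with coarse fixed-width bins, a tight intensity
   cluster can straddle the winning bin's center and the returned threshold
   then cuts inside the cluster.
3. **BV/TV** = foreground pixels / masked pixels (stored as a fraction;
   percentages are a rendering choice).
4. **Tb.Th / Tb.Sp** use Hildebrand-style local thickness: the value at a
   pixel is the diameter of the largest disc contained in the phase that
   covers it, computed from the Euclidean distance transform with disc
   propagation. Two numerical details: the computation runs on a 2×
   supersampled grid, which removes the even/odd parity bias of the
   discrete transform (a straight rod of integer width w then measures
   exactly w, whereas a 1× grid is off by up to 1 px for one parity); and
   the phase is mirror-padded first, so structures cut by the image border
   are closed symmetrically instead of accumulating distance off the edge.
   Accuracy on rod phantoms: ±0.5 px guaranteed by tests; observed ≤ 0.02 px
   (rods) and ≤ 0.015 px (pores).
5. **Tb.N** = BV/TV ÷ Tb.Th, an exact arithmetic identity in the output.
6. **QTS.** The four biomarkers are z-standardized against a reference
   population and projected on the reference's first principal component.
   Orientation is fixed so the BV/TV loading is positive (fallback order if
   a loading vanishes: Tb.N positive, Tb.Sp negative, Tb.Th positive), so
   lower scores mean worse microstructure. A zero-variance reference
   feature is clamped to z = 0 (it drops out of the component); only a
   fully constant reference is an error. The reference population is
   user-supplied (e.g. phantom-derived); this reproduces the construction
   of a PCA composite score, **not** any vendor's proprietary normative
   calibration, and QTS values are therefore comparable only within one
   reference.

## Serum antibody arrays

Per array: protein intensity = mean of its two duplicate spots (a missing
spot leaves NaN, excluding the protein from downstream calls); background =
mean of blank and negative-control spots; normalized intensity =
clip(intensity − background, 0) / (mean positive − background). The exact
vendor normalization is not published; this background-subtract +
positive-anchor scheme is the conventional one and carries a testable
contract: profiles are invariant to a global per-array gain. Fold change of
array t versus basal is (x_t + floor)/(x_basal + floor) with `floor = None`
meaning automatic: 0 when all basal intensities are positive (so planted
fold changes are recovered exactly on clean data), else the smallest
positive normalized intensity (guarding near-blank proteins). Upregulation
is strict: fold change > threshold (default 1.3; 1.30 exactly is not
called). Duplicate averaging precedes normalization; the reverse order is
equivalent up to the clip at zero.

## Circulating miRNAs

Input is a Cq table (miRNA × sample; lower Cq = more abundant). Hemolysis
QC: Δ = Cq(miR-23a-3p) − Cq(miR-451a); fail iff Δ > 7 cycles (strict; the
7-cycle default is the field-standard cut-off for this marker pair and is
configurable, as are the marker and spike-in row ids — the panel is data,
not constants). Missing markers yield "undetermined" rather than a guess.
Normalization: expression = −(Cq_miRNA − Cq_spikein), anchored to the RNA
spike-in added at extraction; per-sample global Cq offsets cancel exactly.
Heatmap preparation: optionally subtract each sample's mean normalized
expression ("global mean" normalization, the convention of the usual
clustering/heatmap tools; separable so it can be switched off), then scale
each row to mean 0, variance 1 (sample sd, ddof = 1); constant rows are
dropped with a warning instead of emitting NaN. Row ordering for heatmaps
reuses the UPGMA clustering from the expression module. Conversion of raw
amplification curves to Cq is instrument firmware and out of scope.

## PedsQL 4.0 scoring

Items are reverse-scored as 100 − 25·response. Domain scores are means of
transformed answered items; the total is the mean over all 23. The missing
rule is the instrument's standard one — a scale with fewer than 50% of its
items answered is not scored (configurable); answered-item means otherwise.
The psychosocial composite (emotional + social + school) is provided as an
optional extra summary. All outputs are bounded in [0, 100] and worsening
any single item can never raise any score.

## Synthetic data: what it does and does not emulate

* **Expression**: per-gene log2 baselines U(3, 9), per-line baseline
  spread (sd 0.5 log2), measurement noise (sd 0.1 log2), a planted
  fraction of genes (10% up, 10% down by default) shifted by ±0.5 log2 in
  every line — sized to a 10-line paired cohort. Values are exponentiated
  to FPKM-like non-negative numbers so the pipeline's log2(x+1)
  re-transform round-trips. Not emulated: count overdispersion, library
  size differences, gene-length effects, correlated gene modules — so the
  recovery results characterize the selector under clean planted effects,
  not RNA-seq noise in full.
* **Phantoms**: straight rod lattices (not stochastic trabeculae), chosen
  so BV/TV, rod width and pore width have closed-form truth; rods are
  centered within each period so the lattice never touches the border.
  Degradations are a linear illumination ramp and Gaussian noise clipped at
  zero. Real trabecular networks are curved, branched and anisotropic;
  phantom accuracy bounds transfer only as a best case.
* **Spot tables**: duplicate spots, three control classes, planted fold
  changes, optional per-array gain and multiplicative spot noise.
* **Cq tables**: spike-in constant up to noise, clean marker gap of 2
  cycles, planted hemolysis samples pushed well past the threshold,
  per-sample global Cq offsets that normalization must cancel.
* **PedsQL**: item responses drawn per respondent from a severity-driven
  binomial, with optional missingness; true scores recorded pre-missingness.

Every generator is a pure function of its config including the seed.

## Problem sizes in tests and the acceptance script

The shipped checks run at desk scale, chosen as the smallest sizes at which
each contract is meaningful: 200 random ≤20-gene tables for the
vote/brute-force equivalence, 20 replicates of a 1000-gene, 10-line cohort
for recovery, 128-px phantoms across rod widths 3–8 px, and a four-member
phantom family for QTS. Larger inputs only change runtime, not the
contracts.

## Known limitations

* The vote selector applies no multiple-testing correction (by design — the
  quorum rule is the guard); interpret single-gene p-values accordingly.
* Local thickness assumes the mask covers the analyzed phases; thickness
  near irregular mask boundaries inherits the mirror-padding approximation.
* QTS depends entirely on the supplied reference population; no normative
  values ship with the package.
* The serum-array normalization is a convention, exact only up to the
  unpublished vendor scheme; its gain-invariance contract is the tested
  property.
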