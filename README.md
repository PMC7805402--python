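# oiserum

Analysis toolkit for mesenchymal stem-cell (MSC) therapy studies in
osteogenesis imperfecta (OI): paired vote-based differential expression,
2-D trabecular bone morphometry from radiographs with a PCA-based quality
score, serum antibody-array fold-change profiling, circulating-miRNA Cq
processing with hemolysis QC, and PedsQL 4.0 quality-of-life scoring — all
backed by seeded synthetic-data generators so every stage is testable
without patient data.

It is aimed at computational biologists re-analyzing small paired cohorts
(cell lines before/after a serum or treatment exposure) and at imaging or
biomarker analysts who need transparent, reproducible reference
implementations of these trial-style analyses.

## The methods

**Vote-based paired DEG selection.** Expression (counts or FPKM, genes ×
samples) is quantile-normalized and stabilized as log2(x+1). For each gene
and each cell line the paired difference d<sub>ℓ</sub> = post − basal is
computed on the log2 scale. In the *up* direction a line votes **for** when
d<sub>ℓ</sub> > +θ<sub>vote</sub> and **against** when d<sub>ℓ</sub> <
−θ<sub>vote</sub> (defaults θ<sub>vote</sub> = 0.1); the *down* direction
mirrors this. A gene is selected in a direction when it gathers at least
`min_votes` (default 9 of 10 lines) **for** votes *and* its one-tailed
paired t-test across lines gives p < α (default 0.05); selected genes are
ranked by ascending p. Companions: highly-variable gene selection, UPGMA
clustering of samples (Euclidean distance, average linkage) and centered
PCA. The selector is an sklearn-style feature selector
(`DemocraticVoteSelector`) so it composes with pipelines;
`democratic_vote()` is the DataFrame-level wrapper.

**Trabecular morphometry.** A radiograph ROI is flat-field corrected
(large-kernel Gaussian background subtraction), binarized by Otsu's
threshold into bone and marrow, and measured:
BV/TV = bone pixels / all pixels; Tb.Th = mean Hildebrand local thickness
(largest inscribed disc) of the bone phase, in mm; Tb.Sp = the same measure
of the marrow phase; Tb.N = BV/TV ÷ Tb.Th (1/mm). The quality trabecular
score (QTS) z-standardizes (BV/TV, Tb.Th, Tb.Sp, Tb.N) against a reference
population and projects onto the reference's first principal component,
oriented so more bone scores higher — lower QTS, higher fracture risk.

**Serum antibody arrays.** Duplicate spots are averaged per protein;
intensities are normalized against blank/negative (background) and positive
(scale anchor) control spots, making profiles invariant to scanner gain.
Fold change versus the basal array flags upregulated proteins
(strictly > 1.3 by default); commonly upregulated sets are intersections
across arrays.

**Circulating miRNAs.** Hemolysis QC from the Cq gap between erythrocyte
miR-451a and stable miR-23a-3p (fail when ΔCq > 7 cycles); relative
expression as −ΔCq versus the RNA spike-in control; optional global-mean
normalization and per-miRNA unit-variance scaling for heatmaps.

**PedsQL 4.0.** 23 items (physical 8, emotional/social/school 5 each) on a
0–4 frequency scale, reverse-scored to 0–100 (0→100 … 4→0); scale scores
are means of answered items, withheld when fewer than half are answered.

## Worked example

```python
from oiserum.synthdata import SimExpressionConfig, simulate_paired_expression, \
    SimPhantomConfig, simulate_phantom
from oiserum.deg import quantile_normalize, log2p1, democratic_vote, VoteConfig
from oiserum.trabecular import analyze_roi

cfg = SimExpressionConfig(n_genes=500, n_lines=10, frac_up=0.1, frac_down=0.1,
                          effect_size=0.5, noise_sd=0.1, seed=7)
matrix, truth = simulate_paired_expression(cfg)
transformed = log2p1(quantile_normalize(matrix))
votes = democratic_vote(transformed, VoteConfig(theta_vote=0.1, min_votes=9, alpha=0.05))
selected = votes[votes["direction"] != "none"]
print(f"selected {len(selected)} genes "
      f"({(selected['direction'] == 'up').sum()} up, {(selected['direction'] == 'down').sum()} down)")

roi, gt = simulate_phantom(SimPhantomConfig(image_size=128, rod_width=4,
                                            rod_spacing=16, pixel_size=0.1))
bm = analyze_roi(roi)
print(f"BV/TV={bm.bvtv:.4f}  Tb.Th={bm.tbth:.3f} mm  Tb.Sp={bm.tbsp:.3f} mm  Tb.N={bm.tbn:.3f} /mm")
```

prints

```
selected 98 genes (50 up, 48 down)
BV/TV=0.2500  Tb.Th=0.400 mm  Tb.Sp=1.200 mm  Tb.N=0.625 /mm
```

100 genes were planted (50 up, 50 down) at a 0.5 log2 effect; the
nine-of-ten vote with the paired-t filter recovers 98 of them with no false
calls. The phantom's rods are 4 px wide every 16 px at 0.1 mm/px, so the
analytic truth is BV/TV = 0.25, Tb.Th = 0.4 mm, Tb.Sp = 1.2 mm and
Tb.N = 0.25/0.4 = 0.625 /mm — recovered exactly.

The same analyses run from the shell:

```bash
oiserum simulate --kind expression --seed 7 --outdir demo
oiserum deg --matrix demo/expression.tsv --pairs demo/pairing.tsv \
            --theta 0.1 --min-votes 9 --alpha 0.05 --outdir demo
```

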