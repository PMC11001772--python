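# sonomorph

Quantitative tooling for **acoustic bioassembly** ("sound patterning") of
microvascular networks: when a shallow, cell-laden liquid is vibrated at a
low frequency (tens of Hz), Faraday standing waves form on its surface and
suspended cells condense beneath the **nodal lines** — the loci of zero
surface displacement.  In a round chamber this produces concentric rings of
densely packed cells; in a square chamber, honeycomb-like lines.  Seeded
endothelial cells and pericytes then self-assemble along these condensates
into capillary-like networks.

`sonomorph` implements the computational chain such an experiment needs,
end to end, together with ground-truth synthetic data so every stage is
testable without a microscope:

1. **Chamber-mode simulation** (`sonomorph.chamber`).  The stationary
   surface displacement of a round chamber mode is
   `ζ(r, θ) = J_m(α_mn · r/R) · cos(mθ)`, with `J_m` the Bessel function of
   the first kind, `α_mn` its n-th positive zero and `R` the domain radius;
   square chambers use the antisymmetric two-mode superposition
   `ζ(x, y) = cos(nπx/lx)cos(mπy/ly) − cos(mπx/lx)cos(nπy/ly)`.  Nodal sets
   are extracted as zero-level contours; an accumulation map converts a
   mode shape into a normalized cell-density ridge of prescribed width.
2. **Synthetic data** (`sonomorph.synth`).  Patterned / random GFP+
   cell-mask images with programmed on-pattern vs background area
   fractions, capillary ribbon networks with programmed per-day width
   distributions, and two-group (n = 3 vs 3) log-normal protein abundance
   tables with programmed up-/down-regulated subsets.  All generators are
   pure functions of (spec, seed) and attach their ground truth.
3. **Morphometrics** (`sonomorph.morphometrics`).  Segmentation, radial
   intensity profiles with peak/valley detection, valley-to-peak ratios and
   FWHM ring thickness, 3-ROI-per-location density-enhancement
   quantification, a from-scratch **local thickness transform** (per-pixel
   largest-inscribed-disc diameter, µm), FFT high-pass filtering, and
   structure-tensor orientation distributions.
4. **Proteomics statistics** (`sonomorph.proteomics`).
   `DifferentialExpression(table).fit()` runs per-protein two-sample
   t-tests on log2 abundances (pooled by default, Welch optional) with
   Benjamini–Hochberg FDR control, and returns a results object with fold
   changes, q-values, direction calls and a `summary()`; PCA scores and
   top-k selection with hierarchical ordering round out the stage.
5. **Protocol arithmetic and orchestration** (`sonomorph.protocol`,
   `sonomorph.pipeline`, CLI `sonomorph`).

## Worked example

```python
from sonomorph import pipeline
manifest, report = pipeline.run_pipeline(seed=5)
```

The default desk-scale run simulates the round m=0, n=4 mode over a 21 mm
domain, renders a 1024² px concentric-ring image programmed with a 438%
on-pattern density enhancement plus a stationary control, quantifies both,
and runs differential expression on a programmed 2000-protein table.  The
report it printed:

```
nodal_radii_mm        [4.2829, 9.8309, 15.4118, 21.0]
n_peaks               4
peak_radii_um         [535.0, 1125.0, 1775.0, 2405.0]
ring_fwhm_um          [115.35, 113.7, 114.93, 58.21]
valley_to_peak_ratio  0.1131
enhancement_pct       {'ring1': 478.0, 'ring2': 476.7}
thickness_by_day      {1: 30.91±8.54, 3: 22.77±9.40, 5: 13.41±3.45} µm
de_counts             {'up': 325, 'down': 133, 'ns': 1542}
pca_explained         [0.8508, 0.0389]
```

Reading it: the four nodal radii sit at `R·α_{0,k}/α_{0,4}` (the boundary
circle r = R = 21 mm included), and the rendered image yields exactly four
radial-profile peaks at the corresponding image radii.  The measured FWHM
ring thickness (~115 µm) is the programmed 100 µm band plus one cell
diameter of edge spill.  The recovered enhancements scatter around the
programmed 438% (a single image pair carries a few-tens-of-percent counting
SD at 5% background coverage — see `docs/methods.md`).  The DE stage calls
325 up / 133 down against the programmed 322/130, the excess being the
false discoveries BH admits at q < 0.05.

The same stages are exposed on the command line:

```sh
sonomorph simulate --shape round --m 0 --n 4 --dim 21 --out field.npy --nodal-out nodal.csv
sonomorph synth image --geometry rings --enhancement 438 --seed 1 --out ring.tif
sonomorph quantify --image ring.tif --pitch 2.5 --what radial --out out/
sonomorph synth proteome --n-up 643 --n-down 261 --seed 1 --out prot
sonomorph de --table prot.tsv --groups prot.groups.tsv --out de/
sonomorph run --seed 1 --out run/
```

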