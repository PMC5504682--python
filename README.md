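# rodquant

Quantitative phenotyping tools for rod-shaped bacteria, built around the
assays used to characterize PLP-binding protein (COG0325/PipY) function in
cyanobacteria:

- **Cell morphometry** (`rodquant.cells`): automatic blur/threshold tuning,
  shape-filtered detection, and cell length/width from the rotated
  minimum-area bounding rectangle (rotating calipers on the convex hull).
- **Inhibition-halo quantification** (`rodquant.halo`): red-channel
  thresholding of disk-diffusion plate photographs, a 3/73/70
  dilate/erode/dilate smoothing cycle that erases artifacts, a moment-based
  ellipse fit, and the halo diameter
  *D* = (major + minor)/2 − disk diameter. The antibiotic **sensitivity** is
  the squared halo radius, *S* = (*D*/2)², which is linear in the amount of
  antibiotic loaded on the disk.
- **Group statistics** (`rodquant.stats`): two-sided Wilcoxon rank-sum
  comparison of length distributions (exact by enumeration for small
  tie-free samples, tie- and continuity-corrected normal approximation
  otherwise), sensitivity-vs-dose linear validation, with/without protection
  ratios, and Tukey boxplot descriptors.
- **Gene-neighborhood statistics** (`rodquant.synteny`): signed intergenic
  distances (*d* = start₂ − end₁ − 1; negative = overlapping ORFs) and
  linkage summaries over GFF3/GenBank annotations, for operon-style
  clusters such as *pipX–pipY–sepF–proC*.
- **Synthetic ground truth** (`rodquant.synth`): every pipeline is testable
  without real data — fields of spherocylindrical cells with known
  lengths/widths/orientations, plate photographs with a lawn, disk filter
  and clearing halo of known diameter over a red background, and toy
  annotations with controlled intergenic gaps and overlaps.

## Worked example

```sh
python examples/compare_populations.py
```

renders two populations of 186 cells whose true mean lengths differ by
14.4% (the magnitude produced by strong PipY overexpression), measures them
with the auto-tuned pipeline, and compares the measured samples:

```
n = 186 vs 186 measured cells
medians: 39.65 vs 46.62 px
mean-length increase: measured 16.5% (true 15.1%)
two-sided rank-sum p = 4.95e-14  (significant at 1e-4)
```

The measured percent increase tracks the generator truth within a couple of
points, and the rank-sum p-value falls far below the p < 0.0001 reporting
threshold used for such comparisons. The other examples cover the halo dose
series (`halo_dose_series.py`, printing measured diameters within 2% of
truth and an R² ≈ 0.998 sensitivity-vs-amount fit), single-field
morphometry (`measure_cell_lengths.py`) and gene-neighborhood arithmetic
(`gene_neighborhood.py`).

A thin CLI mirrors the library for shell use:

```sh
rodquant simulate cells --seed 1 --out run/           # synthetic micrograph + truth CSV
rodquant cells --input run/cells.tiff --min-area 100 --max-area 6000 \
    --elongation-min 1.2 --elongation-max 10 --complexity-max 1.15 \
    --pixel-size 0.1 --out run/measurements.csv
rodquant halo --input plate.png --disk-diameter-mm 6 --pixel-size-mm 0.05
rodquant synteny --annotation genome.gff3 --genes pipX,pipY,sepF,proC --threshold 167
```

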