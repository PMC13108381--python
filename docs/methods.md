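# Methods

`splicemorph` quantifies cell-type-specific gene expression and alternative
splicing from single-cell RNA-seq junction counts, and scores neurovascular
phenotypes from 2D/3D fluorescence microscopy. This note records the models,
the parameters that matter, and the choices made where the design was open.

## Expression normalization, QC and tau

Counts are normalized per cell to counts per million (CPM) against the
cell's total mapped reads (column sums by default; an externally supplied
totals vector overrides, since a count matrix restricted to genes of
interest does not contain the full library). Values are transformed to
log2(CPM + 1), so a raw zero stays zero and CPM 1 maps to exactly 1.

Cell QC screens two per-cell metrics — genes detected (≥1 read) and total
mapped reads — and rejects a cell if either falls strictly below
median − k·MAD across cells, with k = 3 by default. The MAD is unscaled
(median of absolute deviations, no 1.4826 normality factor). When the MAD
degenerates to 0 the threshold equals the median and only strictly-below
cells are rejected; this literal behavior is deliberate and overridable
through k.

Expression specificity uses tau over subclass mean profiles
x = (x_1 … x_n):

    tau = sum_i (1 − x_i / max_j x_j) / (n − 1)

Tau is 0 for a uniform profile, 1 for expression confined to one subclass,
and invariant to positive rescaling. An all-zero profile leaves tau
undefined (flagged NaN) rather than coerced, because the formula divides by
the maximum. Subclass means are plain means of log2(CPM+1); a 25–75%
trimmed-mean variant of the expression gate (closed interquartile interval,
quartile ties included) is used for the "analyzable subclass" decision:
cell count > 100 and trimmed mean > 1.

## Exon inclusion proportions

A transcript including a cassette exon spans two junctions, a skipping
transcript one, so junction reads over-represent inclusion by a factor of
two. The per-cell estimator therefore doubles the exclusion count:

    EIP = I / (I + 2E)

Mutually exclusive splice-site variants a/b within one exon share the
exclusion junction and are constrained to sum to at most 1:

    EIP_a = I_a / (I_a + I_b + E)

A (cell, event) pair is analyzable when inclusion *or* exclusion junction
reads exceed log2(CPM+1) > 1 against the cell's total mapped reads — a
strict inequality, so CPM exactly 1 fails. Subclass summaries average
per-cell EIPs over gated cells (the estimator is defined per cell); pooled
read aggregation is available as an alternative mode. Subclasses
contribute only when they hold more than 100 cells.

Splicing variation is the population variance (ddof 0) of subclass EIPs
per event, complete-case over subclasses; gene totals sum events and
family fractions divide by the family-wide total. The subclass splicing
embedding is a centered, unscaled PCA (numpy SVD); missing entries are a
hard error rather than silently imputed, and component signs are fixed by
making each component's largest-magnitude loading positive so outputs are
reproducible. Coding impact of a cassette exon is pure arithmetic: length,
divisibility by three, and residues = length/3 for in-frame exons. The
packaged `adgrl_exons.tsv` carries the alternatively spliced latrophilin
exon sequences used by the worked examples.

## Synthetic data

The generators define the conditions every estimator is tested under.

* **Junction reads.** Per cell and event, coverage N is negative-binomial
  (mean 50, dispersion 5 by default, emulating Smart-seq depth
  variability; Poisson is the infinite-dispersion limit). Each read is an
  inclusion read with probability 2ψ/(1+ψ), the read-level consequence of
  the two-junctions-per-inclusion geometry, which makes I/(I+2E) unbiased
  for ψ by construction. A small accompanying count matrix with lognormal
  library sizes (median 5×10^5) exercises the CPM gates.
* **Expression counts.** Targets are given as mean log2(CPM+1) per gene
  and subclass. Because the mean of a log lies below the log of a mean,
  drawing counts around 2^μ − 1 would systematically undershoot the
  requested profile; the generator instead calibrates the count mean by
  bisection on the exact NB expectation of log2(CPM+1) at the median
  library size (10^6 by default). Library sizes vary lognormally
  (σ = 0.3).
* **Vessel images.** Networks are line segments with widths in µm;
  rendering anti-aliases tube edges over one pixel and optionally adds
  Gaussian noise and a low-frequency background. Truth length, branch
  points (≥3 segment endpoints coinciding), length-weighted mean width and
  the noiseless mask follow from the geometry.
* **Contact volumes.** A straight tube of radius r along y plus Gaussian
  puncta (σ 0.3 µm lateral / 0.6 µm axial) at constructor-verified signed
  surface distances; voxel anisotropy is honored everywhere.
* **Plate readings.** slope·concentration + intercept + Gaussian noise.

One integer seed drives everything; each generator derives an independent
stream from (seed, stage label), so stages can be regenerated in isolation
and all outputs are bit-reproducible.

What the generators do **not** emulate: batch effects, gene–gene
correlation, PCR duplication, optical aberrations/PSF anisotropy beyond
the Gaussian model, autofluorescence texture, or segmentation-relevant
debris. Passing recovery tests therefore demonstrates estimator
correctness under the stated read/noise models, not robustness to every
artefact of real data.

## Vessel morphometry

The 2D pipeline is: median filter (disk radius 2 px) → CLAHE (clip 0.01)
→ multiscale Frangi vesselness, maximum over scales (1, 1.5, 2, 3) µm
(covering half-widths of 2–6 µm capillaries at the default 0.5 µm/px) →
local adaptive Gaussian threshold (block 121 px, offset 0.02; a pixel is
vessel when its value exceeds the local Gaussian-weighted mean by the
offset, so flat background is suppressed) → removal of connected
components whose maximum inscribed width (2× the peak Euclidean distance
transform) is below 2.0 µm → skeletonization.

Two refinements proved necessary for quantitative recovery and are on by
default. First, segmentation intersects the vesselness threshold with the
same adaptive threshold applied to the preprocessed intensity: a vessel
pixel must be both tubular and bright. Hessian filters emit side-lobe
ridges flanking straight vessels — on noiseless, hard-edged renders the
eigenvalue sign above a perfectly straight edge is degenerate and flips on
sub-1e-4 perturbations — and the intensity gate removes them cleanly.
Second, terminal skeleton twigs shorter than 3 µm that reach a junction
are pruned, and raw branch pixels are defined by the 8-neighborhood
crossing number (≥3 distinct arms) rather than a neighbor count, which
misfires on pixels diagonally flanking a straight line.

Metrics within an optional ROI polygon (µm coordinates, center-in-polygon
rasterization): VAF = 100 × vessel px / ROI px; mean diameter = mean over
skeleton pixels of 2× the distance transform (the standard skeleton-EDT
estimator; the EDT is computed against the full mask so the ROI does not
truncate widths); skeleton length by 8-connected chain length (diagonal
steps √2); branch points consolidated by single-linkage clustering at
10 µm followed by centroid replacement, iterated to a fixed point so the
result respects the separation and is independent of input order. On
noiseless renders the full pipeline recovers truth-mask VAF within 10%
relative, mean diameter within 0.5 µm, and branch counts exactly for
junction separations above 10 µm; these margins are the tested contract,
and the free parameters above were fixed once against them.

## Puncta and surfaces

Spot detection is difference-of-Gaussians: an anisotropic Gaussian matched
to the expected spot FWHM (0.6/0.6/1.2 µm x/y/z by default) minus a 3×
wider Gaussian background estimate. Local maxima above the quality
threshold (a required parameter; there is no sensible universal default)
are refined to sub-voxel centers by a per-axis parabola; symmetric plateau
pairs from boundary-centered spots are resolved by non-maximum suppression
within one expected diameter (quality, then lexicographic order).

Distance from a punctum center to a surface is an anisotropy-corrected
Euclidean distance transform of the surface voxel set, sampled
trilinearly; centers inside the surface are at distance 0. The proximity
cutoff is 1 µm for vessel contacts and 5 µm for nucleus-assigned smFISH
puncta (each punctum to at most one, nearest, nucleus). Per-cell counts
normalize to the image mean (mean of the normalized counts is 1 by
construction).

Surface areas count exposed voxel faces weighted by face dimensions:
exact for axis-aligned boxes, biased upward for smooth surfaces — the
staircase bias for the lateral surface of an axis-aligned cylinder is
exactly 4/π (+27%) — which cancels in the ratio metrics used here
(coverage, per-area densities). When an absolute area matters a marching
cubes estimator (`method="mesh"`, accurate to a few percent on smooth
shapes) is provided. Surface–surface coverage is the percentage of one
surface's exposed-face area lying within a contact radius (default: one
voxel, the largest voxel dimension) of the other, standing in for the
unpublished colocalization tolerance of mesh-based commercial tools.

## Fluorometry

The NaFl standard curve is unweighted ordinary least squares; inversion
flags readings outside the fitted concentration range rather than
refusing them. Tissue content is normalized as concentration × total
extract volume ÷ tissue mass (default extract volume 1200 µl: 500 PBS +
500 TCA + 200 NaOH), and blood–brain barrier permeability is the ratio of
mass-normalized brain to blood content; the ratio is invariant to
rescaling all readings with a refit curve.

## Numerical conventions and degenerate inputs

Zero-total cells are excluded from CPM with a warning; empty subclasses
are dropped with a warning; an event observed in fewer than two subclasses
is skipped by the variance decomposition; an empty vessel mask yields VAF
0 with diameter/density flagged undefined; branch points with zero vessel
length are rejected as inconsistent; an empty surface makes all puncta
non-proximal (warning) but an empty numerator surface in coverage is an
error. All RNG flows through `numpy.random.Generator` seeded per stage.

## Problem sizes

Tests and the acceptance script use 200 cells per subclass at mean depth
50 for splicing recovery, 200–300 cells per subclass for tau recovery,
400×400 px (200×200 µm) vessel renders, and ~100×220×50-voxel contact
volumes — sizes at which the sampling error of every recovery check is
comfortably below its tolerance while the full suite runs in seconds.

## Known limitations

Junction assignment requires exact coordinate matches (no fuzzy matching
of mis-annotated splice sites); multi-mapping junction reads are ignored;
EIP assumes the two inclusion junctions of an event are observed at equal
efficiency; vessel morphometry is 2D and the diameter estimator reports
the inscribed-disk diameter, which undershoots at acute junctions; the
exposed-face area bias makes absolute densities comparable only across
images with equal voxel geometry; spot detection assumes roughly Gaussian,
separated puncta and a required, dataset-specific quality threshold.
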