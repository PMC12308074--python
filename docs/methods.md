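# Methods

## Strain definitions and measurement

All strains are uniaxial engineering strains along the stretch axis
(x = image column). For each cell, lengths are measured on the image row
through the nucleus centroid: the cellular chord L_cell is the contiguous run
of that cell's pixels containing the centroid column, the nuclear chord L_n
the run of nucleus pixels on the same row, and the cytoplasmic chord
L_c = L_cell − L_n. Strains are ε = (L′ − L)/L between the pre- and
post-stretch frames. The chord is the run *containing* the centroid, not the
cell's total occupancy of the row, which keeps the measure well defined for
concave outlines; mid-line chords are a faithful strain read-out because the
applied strains are moderate and the compartments deform approximately
affinely.

Measurement chain and its conventions:

1. **Registration.** Integer-pixel translation maximizing the phase
   correlation of the two frames' cell-boundary images (a confluent
   monolayer's binarized mask is featureless, so label boundaries provide the
   texture). When a bulk stretch separates the frames, the post frame is
   first unstretched along x about the frame centre by the nominal strain;
   the recovered x-shift is scaled back. Sub-pixel registration is not
   attempted. Registration error does not bias strains (chords are measured
   within each frame); it only feeds centroid matching.
2. **Pairing.** Each nucleus is assigned to the cell label under its
   centroid, falling back to maximal pixel overlap when the centroid lands on
   background (ties broken deterministically by overlap then label). Cells
   claimed by two nuclei (mitotic doublets) are excluded; orphan nuclei are
   dropped and counted.
3. **Matching.** Pre/post cells are matched by mutual nearest centroids after
   contracting post-frame x-coordinates by 1/(1+strain) about the frame
   centre. Non-mutual best matches are excluded.
4. **Censoring.** Cells touching the frame edge in either time point have
   incomplete chords and are excluded everywhere. Post-frame border contact
   is detected before the registration shift, since the shift zero-fills the
   margin and would otherwise hide clipped cells.
5. **Chords at integer resolution.** Chords are pixel-run lengths; each
   endpoint carries ±1 px. At 0.25 µm/px with ~30 µm cells this budgets to
   roughly 0.01 strain for ε_cell and 0.02 for ε_n/ε_c, which is what the
   recovery tests assert.

Nuclear size change uses the projected area, ΔA/A, classified as shrink
(≤ −1%), expand (≥ +1%) or no change; chromatin dispersion is proxied by the
change in the within-nucleus intensity coefficient of variation.

## Morphology features

19 features per cell: for the cell and the nucleus each — perimeter, area,
solidity, shape index P/√A, circularity A/P² (deliberately without the 4π
factor, so a disc scores 1/(4π) ≈ 0.0796), aspect ratio, roundness
4A/(π·major²), convex-hull area and convex perimeter — plus the
nucleus-to-cell area ratio as the 19th. The exact published feature list for
this kind of analysis is not standardized; the area ratio is a documented,
swappable choice. Features are computed in pixel units from the label masks
(areas scale as s², perimeters as s under a resolution change s; the CCA
standardizes columns, so units cancel there). Raster perimeter estimates
carry a few percent bias, which the closed-form tests budget for.

## Series-spring partitioning model

The nucleus and cytoplasm are one-dimensional springs in series:
ε_cell = w_n·ε_n + w_c·ε_c with length weights w_n + w_c = 1, and
k = ε_n/ε_c the (inverse) stiffness ratio. The Monte Carlo draws
ε_cell ~ Normal(μ, σ_εcell) and k from a lognormal distribution
(median 0.5 by default: the nucleus deforms half as much as the cytoplasm),
then solves ε_c = ε_cell/(w_n·k + w_c), ε_n = k·ε_c. Viscoelasticity,
plasticity, Poisson coupling and remodelling are deliberately excluded — the
question is only what the partition itself implies.

The closed-form Pearson correlation assumes the equal-length convention
ε_cell = ε_c + ε_n (recovered from the weighted model at w_n = w_c = ½ by
rescaling each strain with its weight):
Cov(ε_c, ε_n) = ½(σ²_εcell − σ²_εc − σ²_εn), hence
r = (σ²_εcell − σ²_εc − σ²_εn)/(2·σ_εc·σ_εn). The ½ matters: without it the
constant-total-strain, equal-sd limit would give −2 instead of the correct
−1. The result is clipped to [−1, 1] with a warning for mutually
inconsistent variance triples.

**Heterogeneity regimes.** Two competing variance sources set the sign of
r: total-strain heterogeneity pushes both compartment strains up and down
together (r → +1 as σ_εcell dominates), while partition-ratio heterogeneity
trades one against the other (r → −1). At μ = 0.25 the crossover for
σ_εcell = 0.15 sits near a lognormal log-sd of ~1.4. The package therefore
defines the broad regime (`BROAD_RATIO`) as log-sd 1.5 — wide enough that
the anti-correlation survives realistic total-strain heterogeneity, weakened
but negative (r ≈ −0.18 at σ_εcell = 0.15; ≈ −0.32 at 0.10) — and the
narrow regime as log-sd 0.5, where it does not (r ≈ +0.66 at
σ_εcell = 0.15). A point-mass ratio makes both strains proportional to
ε_cell (r = +1): no partition heterogeneity, nothing to anti-correlate.

**Parameter recovery.** (σ_εcell, log-sd of k) are recovered from the
observable summary (σ_εc, σ_εn, r) by inverting the forward moment map,
evaluated with Gauss–Hermite quadrature over log k, via bounded least
squares. At n = 2000 the recovery error is a few percent.

## Synthetic monolayer generator

The generator emulates a confluent MDCK-like epithelium: Voronoi cells of a
jittered hexagonal lattice, Lloyd-relaxed (3 iterations) for convex-ish,
space-filling polygons (default ~900 µm² per cell); one nucleus ellipse per
cell (default 20% of cell area — giving mid-line chord fractions near ½ —
aspect ratio 1.2–1.8, random orientation) placed at the cell centroid and
shrunk if needed to keep a margin inside the cell.

**Stretch.** Per cell, ε_cell and k are sampled and the partition solved with
w_n = w_c = ½ by default (per-cell geometric chord fractions are available
via `length_fractions=None`). Each cell carries a piecewise-linear x-map —
slope 1+ε_n over the nucleus mid-line chord, 1+ε_c outside — riding on a
bulk carrier stretch of μ about the field centre. Because independently
sampled strains are geometrically incompatible in a continuous sheet,
per-cell rigid x-shifts are least-squares adjusted (zero-mean gauge) and
shared boundary points averaged between neighbours, keeping the deformed
cells space-filling. The nucleus itself is x-scaled by 1+ε_n about its
centre, so ε_n is exact by construction.

**Two ground truths.** The truth table records both the *drawn* strains and
the strains *realized* by the blended vector geometry along each mid-line
(`eps_*_real`). Under the default heterogeneity the blending shifts ε_c by
up to a few 0.01; the realized values are the ground truth of the rendered
image, and recovery tests compare against them. For a homogeneous stretch
the two coincide exactly.

**Rendering.** 16-bit label masks at 0.25 µm/px by default (cells and
nuclei share labels); the intensity image is 1 inside each nucleus with a
smoothed-noise texture rescaled per nucleus so the within-nucleus CV equals
the requested value exactly (before clipping at 0), and 0 elsewhere. A rigid
global offset (in µm; integer multiples of the pixel size give integer-pixel
shifts) exercises the registration.

**What the generator does not emulate** — and hence what passing tests do
not show about real microscopy: segmentation errors (masks are perfect by
construction), out-of-focus light, z-projection artefacts, cell motility and
junction remodelling between frames, non-convex or multinucleated cells
beyond the constructed fixtures, Poisson contraction in y, and viscoelastic
history. Results on real data inherit whatever error the upstream
segmentation makes.

**Default regime.** mean strain 0.25 (the applied single-stretch amplitude),
σ_εcell = 0.05, broad ratio spread. The strain heterogeneity is kept below
the spring-model's 0.15 because in a *spatially embedded* monolayer large
independent per-cell strains force large boundary-blending corrections;
0.05 keeps the blending sub-pixel-to-pixel scale while still producing a
clearly heterogeneous, strongly anti-correlated population (measured
r ≈ −0.8 on ~90 cells in the demo run).

## Resampling statistics

- Bootstrap p (one-tailed): pairs resampled with replacement; p is the
  fraction of resampled correlations on the opposite side of 0 from the
  tested direction, with the (1+count)/(B+1) correction so 0 is never
  reported. With a pre-specified direction the type-I rate is ~5% at
  α = 0.05 (calibration asserted over 1000 null datasets); letting the data
  choose the tail doubles it, as for any post-hoc one-sided test.
- Permutation FDR: y permuted against x; the estimate is the fraction of
  permuted |r| reaching the observed |r| (two-sided magnitude reading;
  a signed one-sided variant is a flag). Null distribution uniform.
- Correlation comparison between conditions: independent pair-bootstrap of
  each condition, the Δr* distribution re-centred at zero, one-tailed tail
  probability of the observed Δr. Same-data conditions give p ≈ 0.5 exactly;
  same-distribution calibration also requires a pre-specified direction.
- Strain-bin test: ε_c compared between low ([0, 0.15]) and high
  ([0.30, 0.50]) ε_n bins, bounds closed as printed (if the bins touched,
  the shared edge would belong to the low bin); Welch's t-test by default
  (the populations' variances differ), Mann–Whitney as a flag.
- Gaussian histogram fits operate on mean-normalized values, so the fitted
  mean is 1 by construction and the sd is the coefficient of variation.

All procedures are seeded and chunked; n_boot = n_perm = 100 000 defaults
match common practice for stable 4-decimal p-values (unit tests and the demo
config use smaller counts for speed — they are parameters, not constants).

## Canonical correlation analysis

Columns standardized; canonical weights from the SVD of
S_xx^(−1/2)·S_xy·S_yy^(−1/2); correlations clipped to [0, 1]; deterministic
sign convention (largest-magnitude morphology weight positive). A ridge of
1e−8 on the unit-diagonal within-set covariances is always applied: the
feature set is intrinsically near-collinear (convex area equals area for
convex cells; circularity = shape_index^−2), and in the 76-feature
multicellular mode n can approach p. Exact column rescalings leave the
correlations unchanged to 1e−10. No train/test split is used — reported
correlations are in-sample, matching how such analyses are usually
presented; `project_x`/`project_y` support external validation.

The per-strain read-out reports both the best single morphology variate
(the scatter-plot view) and `r_fit`, the correlation with the least-squares
projection onto all variates; only the latter is exactly 1 when the strains
are a linear function of morphology. Multicellular features order neighbours
nearest-first with ties broken by lower label.

## Numerical choices and degenerate inputs

- One master seed per run; per-stage seeds derived via `SeedSequence` (kept
  below 2³¹).
- Sampled ε_cell ≤ −1 (non-physical) is resampled with a warning; k ≤ 0 is
  a parameter error.
- Degenerate bootstrap/permutation resamples (zero variance) are skipped and
  logged; denominators use the valid count.
- Zero-variance inputs to correlation or CCA raise instead of returning NaN.
- Nucleus runs are clipped to the cell run so L_n ≤ L_cell on the raster.
- Voronoi cells are clipped to the field via mirrored seeds, making the
  tessellation exact on the rectangle.

## Known limitations

- Chord strains are 1-D sections; they under-represent cells whose nucleus
  sits off the widest row, and carry integer-pixel quantization.
- The boundary-blending compromise means drawn and realized strains differ
  under strong heterogeneity (both are reported; see above).
- Registration assumes a rigid offset plus a known bulk stretch about the
  frame centre; rotations and non-uniform bulk deformation are out of scope.
- The spring model is elastic and memory-free; cyclic-stretch phenomena are
  represented only through their endpoint strains.
- In-sample CCA correlations are optimistic for small n; use the
  cross-validation hooks when inference matters.
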