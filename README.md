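# strainpart

Quantifying how an epithelial cell partitions an externally applied stretch
between its nucleus and its cytoplasm.

When a confluent monolayer on an elastic membrane is stretched uniaxially,
individual cells do not deform uniformly: the nucleus (stiffer) elongates
less than the cytoplasm, and cells vary in how they split the deformation.
`strainpart` implements the image-analysis and statistics workflow for this
problem, for researchers in cell mechanics and mechanobiology who have
pre/post-stretch segmentation masks (or want a fully synthetic test bed):

- **Strain measurement** from paired label masks: registration of the two
  time points, nucleus–cell pairing, pre/post cell matching, and chord-based
  uniaxial strains. With lengths measured along the stretch (x) axis on the
  row through the nucleus centroid,

  ε_n = ΔL_n/L_n,  ε_c = ΔL_c/L_c,  ε_cell = ΔL_cell/L_cell,

  together with nuclear projected-area change ΔA/A, the change in the
  within-nucleus intensity coefficient of variation (a chromatin-dispersion
  proxy), and 19 morphological features per cell.
- **Series-spring model**: nucleus and cytoplasm as two springs in series,
  ε_cell = w_n·ε_n + w_c·ε_c. Sampling the total strain
  ε_cell ~ N(μ, σ_εcell) and the partition ratio k = ε_n/ε_c independently
  across cells and solving ε_c = ε_cell/(w_n·k + w_c) reproduces the
  characteristic **anti-correlation between nuclear and cytoplasmic strain**.
  Its closed form, under ε_cell = ε_c + ε_n,

  r = (σ²_εcell − σ²_εc − σ²_εn) / (2·σ_εc·σ_εn),

  equals −1 when the total strain is constant across cells (σ_εcell = 0) —
  the two compartment strains then sum to a constant.
- **Resampling statistics**: Fisher-z confidence intervals, one-tailed
  bootstrap p-values (100 000 resamples by default), Monte Carlo permutation
  FDR, pairwise bootstrap comparison of correlations between conditions,
  low/high nuclear-strain group tests, Gaussian fits of mean-normalized
  strain histograms.
- **Canonical correlation analysis** (from first principles) linking the
  three strain components to cell/nuclear morphology, in unicellular (19
  features) and multicellular (own + 3 nearest neighbours, 76 features)
  modes — morphology as a predictor of strain response.
- **Synthetic monolayer generator**: Lloyd-relaxed Voronoi cells with one
  interior nucleus each, deformed by a heterogeneous uniaxial stretch with
  known per-cell ground truth, rasterized to 16-bit label masks plus a
  Hoechst-like intensity image. Every downstream stage is testable without
  microscopy data.

## Worked example

Spring-model Monte Carlo — 2000 cells at 25% mean stretch, 10% total-strain
heterogeneity, broad partition-ratio spread:

```python
from strainpart.spring import SpringParams, simulate_population
from strainpart.synthetic import BROAD_RATIO

pop = simulate_population(
    SpringParams(mean_strain=0.25, sigma_cell_strain=0.10,
                 partition_ratio_dist=BROAD_RATIO, seed=1),
    2000,
)
print(pop.samples[["eps_cell", "eps_n", "eps_c"]].mean().round(3))
print("Pearson(eps_c, eps_n) =", round(pop.pearson_cn(), 3))
```

```
eps_cell    0.249
eps_n       0.186
eps_c       0.311
Pearson(eps_c, eps_n) = -0.324
```

The mean cellular strain tracks the applied 25%; the nucleus elongates less
and the cytoplasm more (the nucleus is stiffer); and across the population
the two compartment strains are anti-correlated — cells whose nucleus
stretches more leave less deformation for the cytoplasm. The closed form
applied to this population's own standard deviations returns the same −0.324.

The full synthetic pipeline (simulate → measure → stats → cca):

```bash
strainpart run --seed 1 --out demo_run
```

produces per-cell strain and morphology tables and, in
`demo_run/stats_report.json` (90 interior cells measured from the rendered
masks):

```
r = -0.780, 95% CI [-0.850, -0.683], bootstrap p = 1e-04, Monte Carlo FDR = 1e-04
low-bin (eps_n in [0, 0.15]) mean eps_c = 0.403 vs high-bin ([0.30, 0.50]) 0.144
```

i.e. the anti-correlation generated in the ground truth is recovered from the
rendered images, and cells with small nuclear strain show significantly
larger cytoplasmic strain. `demo_run/cca.json` reports the canonical
correlations of morphology vs strain for the same cells.

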