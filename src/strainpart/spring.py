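"""One-dimensional series-spring model of nucleus/cytoplasm strain partitioning.

The nucleus and cytoplasm are modelled as two springs in series along the
stretch axis. A cell's total strain is the length-weighted sum of the
compartment strains,

    ϵcell = wn·ϵn + wc·ϵc,        wn + wc = 1,

and the partition ratio k = ϵn/ϵc encodes the (inverse) stiffness ratio of the
compartments. Sampling ϵcell and k independently across a population and
solving the partition produces the characteristic anti-correlation between
cytoplasmic and nuclear strain: with equal compartment lengths and a constant
total strain the two strains sum to a constant and the Pearson correlation is
exactly −1; total-strain heterogeneity weakens (but preserves) the
anti-correlation, while partition-ratio heterogeneity strengthens it.

The closed-form correlation used throughout assumes ϵcell = ϵc + ϵn (the
equal-length derivation, recovered from the weighted model at wn = wc = ½
after rescaling each strain by its length weight):

    Cov(ϵc, ϵn) = ½(σϵcell² − σϵc² − σϵn²),
    r = Cov(ϵc, ϵn)/(σϵc·σϵn).

Higher-order mechanics (viscoelasticity, plasticity, Poisson effects,
remodelling) are deliberately excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic import RatioDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "SpringParams",
    "SpringPopulation",
    "VarianceTriple",
    "simulate_population",
    "analytic_pearson",
    "regime_sweep",
    "fit_spring_params",
]


@dataclass(frozen=True)
class SpringParams:
    """Monte Carlo parameters: Normal(mean_strain, sigma_cell_strain) total
    strain, ratio distribution for k = ϵn/ϵc, and length weights (wn, wc)."""

    mean_strain: float = 0.25
    sigma_cell_strain: float = 0.15
    partition_ratio_dist: RatioDistribution = RatioDistribution()
    length_fractions: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_cell_strain < 0:
            raise ValueError("sigma_cell_strain must be >= 0")
        wn, wc = self.length_fractions
        if not (0 < wn < 1 and 0 < wc < 1) or abs(wn + wc - 1) > 1e-9:
            raise ValueError("length fractions must lie in (0,1) and sum to 1")


@dataclass
class SpringPopulation:
    """A simulated population: per-cell (ϵcell, ϵn, ϵc, k) and its parameters."""

    samples: pd.DataFrame
    params: SpringParams

    @property
    def n(self) -> int:
        return len(self.samples)

    def pearson_cn(self) -> float:
        """Sample Pearson correlation between ϵc and ϵn."""
        return float(np.corrcoef(self.samples["eps_c"], self.samples["eps_n"])[0, 1])

    def variance_triple(self) -> "VarianceTriple":
        s = self.samples
        return VarianceTriple(
            sigma_cell=float(s["eps_cell"].std(ddof=1)),
            sigma_c=float(s["eps_c"].std(ddof=1)),
            sigma_n=float(s["eps_n"].std(ddof=1)),
        )


@dataclass(frozen=True)
class VarianceTriple:
    """Standard deviations of the cellular, cytoplasmic and nuclear strains."""

    sigma_cell: float
    sigma_c: float
    sigma_n: float

    def __post_init__(self) -> None:
        if min(self.sigma_cell, self.sigma_c, self.sigma_n) < 0:
            raise ValueError("standard deviations must be >= 0")


def simulate_population(params: SpringParams, n: int) -> SpringPopulation:
    """Draw ``n`` cells: ϵcell ~ Normal, k ~ ratio distribution, partition solved.

    ϵc = ϵcell/(wn·k + wc) and ϵn = k·ϵc, so every sample satisfies the
    series-spring identity ϵcell = wn·ϵn + wc·ϵc to machine precision.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(params.seed)
    eps_cell = rng.normal(params.mean_strain, params.sigma_cell_strain, n)
    k = params.partition_ratio_dist.sample(rng, n)
    wn, wc = params.length_fractions
    eps_c = eps_cell / (wn * k + wc)
    eps_n = k * eps_c
    samples = pd.DataFrame(
        {"eps_cell": eps_cell, "eps_n": eps_n, "eps_c": eps_c, "k": k}
    )
    return SpringPopulation(samples=samples, params=params)


def analytic_pearson(v: VarianceTriple | None = None, *,
                     sigma_cell: float | None = None,
                     sigma_c: float | None = None,
                     sigma_n: float | None = None) -> float:
    """Closed-form Pearson correlation between ϵc and ϵn.

    Under ϵcell = ϵc + ϵn, the covariance is ½(σϵcell² − σϵc² − σϵn²), so

        r = (σϵcell² − σϵc² − σϵn²) / (2·σϵc·σϵn).

    The result is clipped to [−1, 1] with a warning when the supplied
    variances are mutually inconsistent. σϵc = σϵn with σϵcell = 0 gives
    exactly −1 (perfect anti-correlation).
    """
    if v is None:
        v = VarianceTriple(sigma_cell, sigma_c, sigma_n)
    if v.sigma_c <= 0 or v.sigma_n <= 0:
        raise ValueError("undefined correlation: sigma_c and sigma_n must be > 0")
    r = (v.sigma_cell**2 - v.sigma_c**2 - v.sigma_n**2) / (2.0 * v.sigma_c * v.sigma_n)
    if r < -1.0 or r > 1.0:
        warnings.warn(
            f"inconsistent variance triple (raw r = {r:.4g}); clipping to [-1, 1]",
            RuntimeWarning,
            stacklevel=2,
        )
        r = float(np.clip(r, -1.0, 1.0))
    return float(r)


def regime_sweep(
    sigma_cell_values,
    sigma_log_values,
    n: int = 2000,
    seed: int = 0,
    n_boot: int = 500,
    mean_strain: float = 0.25,
    ratio_median: float = 0.5,
) -> pd.DataFrame:
    """Empirical Pearson(ϵc, ϵn) with bootstrap CI over a heterogeneity grid.

    One row per (σϵcell, k log-sd) pair. At fixed σϵcell the anti-correlation
    deepens (r decreases) as the partition-ratio spread grows.
    """
    sigma_cell_values = np.atleast_1d(np.asarray(sigma_cell_values, dtype=float))
    sigma_log_values = np.atleast_1d(np.asarray(sigma_log_values, dtype=float))
    if sigma_cell_values.size == 0 or sigma_log_values.size == 0:
        raise ValueError("grid must be non-empty")
    rows = []
    master = np.random.SeedSequence(seed)
    for sc in sigma_cell_values:
        for sl in sigma_log_values:
            sub = master.spawn(1)[0]
            pop_seed, boot_seed = sub.generate_state(2) % (2**31)
            pop = simulate_population(
                SpringParams(
                    mean_strain=mean_strain,
                    sigma_cell_strain=float(sc),
                    partition_ratio_dist=RatioDistribution("lognormal", ratio_median, float(sl)),
                    seed=int(pop_seed),
                ),
                n,
            )
            r = pop.pearson_cn()
            rng = np.random.default_rng(int(boot_seed))
            ec = pop.samples["eps_c"].to_numpy()
            en = pop.samples["eps_n"].to_numpy()
            rs = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.integers(0, n, n)
                with np.errstate(invalid="ignore"):
                    rs[b] = np.corrcoef(ec[idx], en[idx])[0, 1]
            rs = rs[np.isfinite(rs)]
            lo, hi = (np.percentile(rs, [2.5, 97.5]) if rs.size else (np.nan, np.nan))
            rows.append(
                {
                    "sigma_cell_strain": float(sc),
                    "ratio_sigma_log": float(sl),
                    "r": r,
                    "ci_lo": float(lo),
                    "ci_hi": float(hi),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# parameter recovery
# --------------------------------------------------------------------------- #


def _lognormal_partition_moments(sigma_log: float, median: float, wn: float,
                                 n_nodes: int = 81) -> dict[str, float]:
    """Gauss–Hermite moments of g = 1/(wn·k + wc) and k·g for lognormal k."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / weights.sum()
    k = median * np.exp(sigma_log * nodes)
    g = 1.0 / (wn * k + (1.0 - wn))
    return {
        "g": float(w @ g),
        "g2": float(w @ g**2),
        "kg": float(w @ (k * g)),
        "k2g2": float(w @ (k * g) ** 2),
        "kg2": float(w @ (k * g**2)),
    }


def predicted_summary(sigma_cell: float, sigma_log: float, mean_strain: float,
                      ratio_median: float, wn: float) -> tuple[float, float, float]:
    """Model-implied (σϵc, σϵn, r) for given heterogeneity parameters."""
    m = _lognormal_partition_moments(sigma_log, ratio_median, wn)
    mu2 = mean_strain**2 + sigma_cell**2
    var_c = mu2 * m["g2"] - (mean_strain * m["g"]) ** 2
    var_n = mu2 * m["k2g2"] - (mean_strain * m["kg"]) ** 2
    cov = mu2 * m["kg2"] - mean_strain**2 * m["g"] * m["kg"]
    r = cov / np.sqrt(var_c * var_n)
    return float(np.sqrt(var_c)), float(np.sqrt(var_n)), float(r)


def fit_spring_params(
    sigma_c: float,
    sigma_n: float,
    r: float,
    mean_strain: float = 0.25,
    ratio_median: float = 0.5,
    wn: float = 0.5,
) -> tuple[float, float]:
    """Recover (σϵcell, k log-sd) by matching (σϵc, σϵn, r).

    The forward map from the two heterogeneity parameters to the observable
    summary (σϵc, σϵn, r) is evaluated by quadrature and inverted by bounded
    least squares. Returns ``(sigma_cell_strain, ratio_sigma_log)``.
    """
    target = np.array([sigma_c, sigma_n, r])
    scale = np.array([max(sigma_c, 1e-6), max(sigma_n, 1e-6), 1.0])

    def resid(theta):
        pred = predicted_summary(theta[0], theta[1], mean_strain, ratio_median, wn)
        return (np.array(pred) - target) / scale

    sol = optimize.least_squares(
        resid,
        x0=[0.1, 0.4],
        bounds=([0.0, 1e-4], [2.0, 3.0]),
        xtol=1e-12,
        ftol=1e-12,
    )
    return float(sol.x[0]), float(sol.x[1])
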