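"""Resampling statistics for strain correlations.

Implements the inference toolbox used around the Pearson correlation read-out:
Fisher-z confidence intervals, one-tailed bootstrap p-values, a Monte Carlo
permutation estimate of the false discovery rate, a pairwise bootstrap
comparison of correlation coefficients between conditions, the low/high
nuclear-strain group test and Gaussian fits of mean-normalized histograms.

All resampling procedures are seeded and deterministic, and all p-values use
the (1 + count)/(B + 1) small-sample correction so an exact zero is never
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationReport",
    "GaussianFit",
    "pearson_ci",
    "bootstrap_pvalue",
    "permutation_fdr",
    "compare_correlations",
    "strain_bin_test",
    "gaussian_fit",
    "correlation_report",
]

_CHUNK = 20_000


def _validate_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    return x, y


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def _pearson_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for equally shaped (B, n) matrices; NaN if degenerate."""
    xm = xs - xs.mean(axis=1, keepdims=True)
    ym = ys - ys.mean(axis=1, keepdims=True)
    num = (xm * ym).sum(axis=1)
    den = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def pearson_ci(x, y, confidence: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Sample Pearson r with a Fisher z-transform confidence interval."""
    x, y = _validate_xy(x, y)
    r = _pearson(x, y)
    n = len(x)
    if n <= 3 or abs(r) == 1.0:
        return r, (r, r)
    z = np.arctanh(r)
    half = sps.norm.ppf(0.5 + confidence / 2) / np.sqrt(n - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def _bootstrap_r(x, y, n_boot, rng) -> tuple[np.ndarray, int]:
    """Bootstrap distribution of r (pairs resampled with replacement)."""
    n = len(x)
    out = np.empty(n_boot)
    pos = 0
    for start in range(0, n_boot, _CHUNK):
        b = min(_CHUNK, n_boot - start)
        idx = rng.integers(0, n, (b, n))
        out[pos : pos + b] = _pearson_rows(x[idx], y[idx])
        pos += b
    finite = np.isfinite(out)
    skipped = int(n_boot - finite.sum())
    if skipped:
        logger.info("skipped %d degenerate bootstrap resamples", skipped)
    return out[finite], skipped


def bootstrap_pvalue(
    x,
    y,
    n_boot: int = 100_000,
    direction: str | None = None,
    seed: int = 0,
) -> float:
    """One-tailed bootstrap p-value for a Pearson correlation.

    Pairs are resampled with replacement ``n_boot`` times; the p-value is the
    proportion of resampled coefficients lying on the opposite side of zero
    from the tested direction (i.e. contradicting the alternative), with the
    +1 correction:  p = (1 + #{r* opposite or beyond 0}) / (B + 1).

    ``direction`` is "negative" or "positive"; ``None`` uses the sign of the
    observed correlation. Fixing the direction a priori gives a calibrated 5%
    type-I rate at α = 0.05 under independence.
    """
    x, y = _validate_xy(x, y)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    r_obs = _pearson(x, y)
    if direction is None:
        direction = "negative" if r_obs < 0 else "positive"
    if direction not in {"negative", "positive"}:
        raise ValueError("direction must be 'negative', 'positive' or None")
    rs, _ = _bootstrap_r(x, y, n_boot, np.random.default_rng(seed))
    extreme = (rs >= 0).sum() if direction == "negative" else (rs <= 0).sum()
    return float((1 + extreme) / (len(rs) + 1))


def permutation_fdr(
    x,
    y,
    n_perm: int = 100_000,
    seed: int = 0,
    two_sided: bool = True,
) -> float:
    """Monte Carlo FDR for an observed correlation via permutation.

    y is randomly permuted against x ``n_perm`` times to destroy any pairing;
    the FDR estimate is the proportion of permuted correlations whose
    magnitude reaches the observed one (``two_sided=False`` compares signed
    values in the direction of the observed r instead), with the +1
    correction. Under the null the estimate is uniform on (0, 1).
    """
    x, y = _validate_xy(x, y)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    r_obs = _pearson(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    count = 0
    valid = 0
    for start in range(0, n_perm, _CHUNK):
        b = min(_CHUNK, n_perm - start)
        perm = np.tile(y, (b, 1))
        perm = rng.permuted(perm, axis=1)
        rs = _pearson_rows(np.tile(x, (b, 1)), perm)
        rs = rs[np.isfinite(rs)]
        valid += rs.size
        if two_sided:
            count += int((np.abs(rs) >= abs(r_obs)).sum())
        elif r_obs < 0:
            count += int((rs <= r_obs).sum())
        else:
            count += int((rs >= r_obs).sum())
    return float((1 + count) / (valid + 1))


def compare_correlations(
    x_a,
    y_a,
    x_b,
    y_b,
    n_resample: int = 100_000,
    direction: str | None = None,
    seed: int = 0,
) -> float:
    """One-tailed bootstrap p-value for a difference in Pearson correlations.

    Each condition is resampled with replacement to build the empirical
    distribution of Δr* = r*_A − r*_B, which is re-centred at zero (the null
    of no true difference); the p-value is the proportion of re-centred
    differences at least as extreme as the observed Δr in its direction.
    """
    x_a, y_a = _validate_xy(x_a, y_a)
    x_b, y_b = _validate_xy(x_b, y_b)
    if n_resample < 1:
        raise ValueError("n_resample must be >= 1")
    r_a = _pearson(x_a, y_a)
    r_b = _pearson(x_b, y_b)
    delta_obs = r_a - r_b
    if direction is None:
        direction = "negative" if delta_obs < 0 else "positive"
    ss = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    rs_a, _ = _bootstrap_r(x_a, y_a, n_resample, np.random.default_rng(int(ss[0])))
    rs_b, _ = _bootstrap_r(x_b, y_b, n_resample, np.random.default_rng(int(ss[1])))
    m = min(len(rs_a), len(rs_b))
    delta = rs_a[:m] - rs_b[:m]
    delta0 = delta - delta.mean()  # null distribution centred at zero
    if direction == "negative":
        extreme = int((delta0 <= delta_obs).sum())
    else:
        extreme = int((delta0 >= delta_obs).sum())
    return float((1 + extreme) / (m + 1))


def strain_bin_test(
    strain_table: pd.DataFrame,
    low: tuple[float, float] = (0.0, 0.15),
    high: tuple[float, float] = (0.30, 0.50),
    test: str = "welch",
) -> dict:
    """Compare cytoplasmic strain between low and high nuclear-strain groups.

    Cells are binned by ϵn into ``low`` and ``high`` intervals (closed at the
    printed bounds; the shared edge, if the bins touch, belongs to the low
    bin) and the group means of ϵc are compared with Welch's t-test
    (``test="mannwhitney"`` for the rank alternative).
    """
    eps_n = strain_table["eps_n"].to_numpy(dtype=float)
    eps_c = strain_table["eps_c"].to_numpy(dtype=float)
    in_low = (eps_n >= low[0]) & (eps_n <= low[1])
    if high[0] == low[1]:
        in_high = (eps_n > high[0]) & (eps_n <= high[1])
    else:
        in_high = (eps_n >= high[0]) & (eps_n <= high[1])
    for name, mask in (("low", in_low), ("high", in_high)):
        if mask.sum() < 2:
            raise ValueError(f"strain bin '{name}' contains fewer than 2 cells")
    a, b = eps_c[in_low], eps_c[in_high]
    if test == "welch":
        stat, p = sps.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError("test must be 'welch' or 'mannwhitney'")
    return {
        "mean_low": float(a.mean()),
        "mean_high": float(b.mean()),
        "n_low": int(in_low.sum()),
        "n_high": int(in_high.sum()),
        "statistic": float(stat),
        "p_value": float(p),
        "test": test,
    }


@dataclass(frozen=True)
class GaussianFit:
    """Maximum-likelihood normal fit of mean-normalized values."""

    mean: float
    sd: float

    def pdf(self, x) -> np.ndarray:
        if self.sd == 0:
            raise ValueError("degenerate fit: sd = 0")
        return sps.norm.pdf(np.asarray(x, dtype=float), self.mean, self.sd)


def gaussian_fit(values) -> GaussianFit:
    """Fit a Gaussian to values normalized by their mean (histogram overlay).

    Each strain distribution is normalized to its mean before fitting, so the
    fitted mean is 1 by construction and the fitted sd is the coefficient of
    variation of the raw values.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    mean0 = values.mean()
    if mean0 == 0:
        raise ValueError("cannot mean-normalize values with zero mean")
    z = values / mean0
    return GaussianFit(mean=float(z.mean()), sd=float(z.std(ddof=0)))


@dataclass
class CorrelationReport:
    """Full correlation read-out: r, CI, bootstrap p, Monte Carlo FDR."""

    r: float
    ci95: tuple[float, float]
    p_boot: float
    fdr_mc: float
    n: int
    n_boot: int
    n_perm: int
    seed: int
    direction: str

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95"] = list(d["ci95"])
        return d


def correlation_report(
    x,
    y,
    n_boot: int = 100_000,
    n_perm: int = 100_000,
    direction: str | None = None,
    seed: int = 0,
) -> CorrelationReport:
    """Convenience wrapper: Pearson r + CI + bootstrap p + permutation FDR."""
    x, y = _validate_xy(x, y)
    r, ci = pearson_ci(x, y)
    if direction is None:
        direction = "negative" if r < 0 else "positive"
    sub = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    p = bootstrap_pvalue(x, y, n_boot=n_boot, direction=direction, seed=int(sub[0]))
    fdr = permutation_fdr(x, y, n_perm=n_perm, seed=int(sub[1]))
    return CorrelationReport(
        r=r,
        ci95=ci,
        p_boot=p,
        fdr_mc=fdr,
        n=len(x),
        n_boot=n_boot,
        n_perm=n_perm,
        seed=seed,
        direction=direction,
    )
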