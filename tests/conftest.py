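import numpy as np
import pytest

from strainpart import measure as me
from strainpart import synthetic as sy


@pytest.fixture(scope="session")
def hetero_monolayer():
    """A heterogeneous 80-cell monolayer pair: geometry, frames and tables.

    Default stretch regime (25% mean strain, 5% strain heterogeneity, broad
    partition-ratio spread) with a rigid (8, 2)-pixel offset, rendered at
    0.25 µm/px.
    """
    geom = sy.generate_geometry(80, seed=3)
    post_geom = sy.apply_stretch(geom, sy.StretchParams(global_offset=(2.0, 0.5), seed=11))
    pre = sy.render_frame(geom, 0.25, intensity_cv=0.15, seed=5)
    post = sy.render_frame(post_geom, 0.25, intensity_cv=0.15, seed=6)
    strain_table, morph, diag = me.measure_pair(pre, post, strain_guess=0.25)
    return {
        "geom": geom,
        "post_geom": post_geom,
        "pre": pre,
        "post": post,
        "strain_table": strain_table,
        "morphology": morph,
        "diagnostics": diag,
        "truth": post_geom.true_strain.set_index("cell_id"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def brute_force_rho1():
    """Independent CCA oracle: direct numerical maximization of |corr(Xa, Yb)|."""
    from scipy.optimize import minimize

    def _oracle(X, Y, restarts=6, seed=0):
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        p, q = Xc.shape[1], Yc.shape[1]
        gen = np.random.default_rng(seed)

        def neg(theta):
            u, v = Xc @ theta[:p], Yc @ theta[p:]
            if u.std() == 0 or v.std() == 0:
                return 0.0
            return -abs(float(np.corrcoef(u, v)[0, 1]))

        best = 0.0
        for _ in range(restarts):
            res = minimize(neg, gen.normal(size=p + q), method="BFGS",
                           options={"gtol": 1e-10, "maxiter": 2000})
            best = max(best, -res.fun)
        return best

    return _oracle
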