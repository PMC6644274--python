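"""Independent brute-force oracles used to cross-check the implementation.

Each oracle takes a deliberately different computational route from the
code it checks: dense sampling + bisection instead of a closed form,
residual regressions instead of the first-order partial-correlation
formula, explicit normal equations instead of the fitted OLS, and a
general-purpose minimizer instead of the linear circle-fit solve.
"""

from __future__ import annotations

import numpy as np


def esd_sampling_oracle(z_a, r_a, z_p, r_p, n_grid=20001, tol=1e-12):
    """Depth of the circle–circle crossing by dense sampling + bisection.

    Walks the upper half of the anterior circle, finds where its distance
    to the posterior centre crosses the posterior radius, and bisects the
    bracketing arc.  Returns the crossing point's depth, or None if the
    circles do not cross.
    """

    def f(t):
        z = z_a + r_a * np.cos(t)
        h = r_a * np.sin(t)
        return (z - z_p) ** 2 + h**2 - r_p**2

    ts = np.linspace(1e-9, np.pi - 1e-9, n_grid)
    vals = f(ts)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        return None
    lo, hi = ts[sign_change[0]], ts[sign_change[0] + 1]
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    t = (lo + hi) / 2
    return float(z_a + r_a * np.cos(t))


def residual_partial_corr(x, y, z):
    """Partial correlation by correlating residuals of x~z and y~z."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    design = np.column_stack([np.ones_like(z), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(
        np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    )


def normal_equations_ols(y, X):
    """OLS coefficients (intercept first) by explicit normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones(len(y)), X])
    xtx = design.T @ design
    beta = np.linalg.inv(xtx) @ design.T @ y
    resid = y - design @ beta
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    return beta, float(r2)


def kasa_objective(points, center_depth, center_height, radius):
    """The algebraic circle-fit objective evaluated at a candidate circle."""
    z, h = points[:, 0], points[:, 1]
    # z² + h² + Dz + Eh + F with D = −2 zc, E = −2 hc, F = zc²+hc²−r².
    d, e = -2.0 * center_depth, -2.0 * center_height
    f = center_depth**2 + center_height**2 - radius**2
    return float(np.sum((z**2 + h**2 + d * z + e * h + f) ** 2))
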