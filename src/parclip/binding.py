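"""Single-site quadratic binding model and anisotropy titration fitting.

When the labeled nucleic-acid concentration L is comparable to the
dissociation constant, the free-protein approximation of the hyperbolic
isotherm fails (ligand depletion). The fraction bound then follows the
quadratic solution of the binding equilibrium

    y(x) = Bmax * ((x + L + Kd) - sqrt((x + L + Kd)^2 - 4 x L)) / (2 L)

with x the total protein concentration. Fitting recovers the apparent
dissociation constant ``kd_app`` and the signal amplitude ``bmax`` by
least squares with multistart initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class TitrationCurve:
    """One titration series: protein concentrations x (nM, ascending,
    including 0), response y (relative anisotropy change), and the labeled
    nucleic-acid concentration L (nM)."""

    x: np.ndarray
    y: np.ndarray
    L: float
    replicate: str = "r1"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(x < 0):
            raise ValueError("protein concentrations must be >= 0")
        if self.L <= 0:
            raise ValueError("ligand concentration L must be > 0")
        order = np.argsort(x, kind="stable")
        object.__setattr__(self, "x", x[order])
        object.__setattr__(self, "y", y[order])


@dataclass(frozen=True)
class BindingFit:
    kd_app: float
    bmax: float
    kd_se: float
    bmax_se: float
    rss: float
    n_points: int
    converged: bool
    depletion_limited: bool = False


def binding_model(x, L: float, kd: float, bmax: float):
    """Quadratic (ligand-depletion) single-site isotherm; 0 <= y <= bmax."""
    x = np.asarray(x, dtype=float)
    if L <= 0 or kd <= 0:
        raise ValueError("L and kd must be > 0")
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    s = x + L + kd
    disc = s * s - 4.0 * x * L
    # algebraically >= (x - L)^2 + kd^2 > 0; clip guards rounding only
    y = bmax * (s - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * L)
    return y if y.ndim else float(y)


def _kd_guess(x: np.ndarray, y: np.ndarray) -> float:
    """x at half-maximal response by linear interpolation."""
    ymax = float(np.max(y))
    half = ymax / 2.0
    above = np.flatnonzero(y >= half)
    if len(above) == 0 or above[0] == 0:
        return float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    j = above[0]
    x0, x1, y0, y1 = x[j - 1], x[j], y[j - 1], y[j]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def fit_binding(
    curves: TitrationCurve | list[TitrationCurve],
    n_starts: int = 5,
    ftol: float = 1e-12,
) -> BindingFit:
    """Least-squares fit of (kd_app, bmax), replicates pooled jointly.

    Starts from bmax = max(y) and kd = x at half-max, plus log-spaced kd
    perturbations spanning two decades; the best converged start wins.
    A fit with kd_app below L/2 is flagged depletion-limited: in that
    regime the curve shape carries little information about kd.
    """
    if isinstance(curves, TitrationCurve):
        curves = [curves]
    if not curves:
        raise ValueError("no titration curves supplied")
    L = curves[0].L
    if any(c.L != L for c in curves):
        raise ValueError("replicates must share the ligand concentration L")
    x = np.concatenate([c.x for c in curves])
    y = np.concatenate([c.y for c in curves])
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct protein concentrations")
    if np.allclose(y, y[0]):
        return BindingFit(np.nan, np.nan, np.nan, np.nan,
                          float(np.sum((y - y.mean()) ** 2)), len(y), False)

    def residuals(theta):
        kd, bmax = theta
        return binding_model(x, L, kd, bmax) - y

    kd0 = max(_kd_guess(x, y), 1e-3)
    bmax0 = float(np.max(y))
    offsets = np.logspace(-1.0, 1.0, n_starts)
    best = None
    for f in offsets:
        try:
            res = least_squares(residuals, x0=[kd0 * f, bmax0],
                                bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                                ftol=ftol, xtol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        return BindingFit(np.nan, np.nan, np.nan, np.nan, np.nan, len(y), False)

    rss, res = best
    kd, bmax = res.x
    dof = max(len(y) - 2, 1)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * rss / dof
        kd_se, bmax_se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        kd_se = bmax_se = np.nan
    return BindingFit(kd_app=float(kd), bmax=float(bmax), kd_se=kd_se,
                      bmax_se=bmax_se, rss=rss, n_points=len(y), converged=True,
                      depletion_limited=bool(kd < L / 2.0))
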