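"""Confidence-rating ROC construction and DPSD model fitting.

The receiver-operating characteristic is built cumulatively over the six
confidence levels: point *i* pairs the proportion of lures and the
proportion of targets answered at levels 1..i (most-confident-old first).
The sixth point is (1, 1) by construction and excluded, leaving five
coordinates per ROC.

The dual-process signal-detection (DPSD) model predicts these points as

    p_fa(c)  = Phi(-c)
    p_hit(c) = R + (1 - R) * Phi(F - c)

with recollection probability R in [0, 1], familiarity sensitivity F >= 0,
and criteria c1 > ... > c5.  Parameters minimize the summed squared
residuals in both coordinates over the five points.  If the best-fitting R
over the relaxed range [-1, 1] is negative, R is fixed to 0 and the model
refit (negative recollection has no meaning beyond zero recollection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr, ndtri

__all__ = ["ROCPoints", "DPSDFit", "build_roc", "dpsd_predict", "fit_dpsd"]


@dataclass(frozen=True)
class ROCPoints:
    """Five cumulative (false-alarm, hit) coordinates, strict to liberal."""

    fa: tuple
    hit: tuple
    n_target: int
    n_lure: int

    def __post_init__(self):
        fa, hit = np.asarray(self.fa), np.asarray(self.hit)
        if fa.shape != (5,) or hit.shape != (5,):
            raise ValueError("ROC requires exactly 5 coordinate pairs")
        for name, v in (("fa", fa), ("hit", hit)):
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} rates must lie in [0, 1]")
            if np.any(np.diff(v) < 0):
                raise ValueError(f"cumulative {name} rates must be nondecreasing")


@dataclass(frozen=True)
class DPSDFit:
    """Fitted DPSD parameters.

    ``R`` is the recollection index, ``F`` the familiarity index (d'_F with
    unit lure standard deviation), ``criteria`` the five decision
    thresholds from strictest to most liberal.  ``refit_applied`` records
    that the relaxed fit produced R < 0 and the model was refit with R = 0.
    The lure-recollection parameter is fixed at 0 and the familiarity
    standard deviation at 1.
    """

    R: float
    F: float
    criteria: tuple
    sse: float
    refit_applied: bool
    degenerate: bool = False
    R_n: float = 0.0
    sigma_F: float = 1.0


def build_roc(records) -> ROCPoints:
    """Cumulative confidence ROC from response records.

    ``records`` is an iterable of objects (or a DataFrame) with
    ``trial_type`` (match/nonmatch) and ``level`` (1..6) fields.  Point i
    uses responses at confidence levels <= i, cumulating from level 1
    (*absolutely certain old*).
    """
    import pandas as pd

    if isinstance(records, pd.DataFrame):
        levels = records["level"].to_numpy()
        is_match = records["trial_type"].to_numpy() == "match"
    else:
        records = list(records)
        levels = np.array([r.level for r in records])
        is_match = np.array([r.trial_type == "match" for r in records])
    n_target = int(is_match.sum())
    n_lure = int((~is_match).sum())
    if n_target == 0 or n_lure == 0:
        raise ValueError(
            f"ROC needs both trial types: {n_target} match, {n_lure} nonmatch"
        )
    hit = tuple((levels[is_match] <= i).mean() for i in range(1, 6))
    fa = tuple((levels[~is_match] <= i).mean() for i in range(1, 6))
    return ROCPoints(fa=fa, hit=hit, n_target=n_target, n_lure=n_lure)


def dpsd_predict(R: float, F: float, c) -> tuple:
    """Model-predicted cumulative (p_fa, p_hit) at criterion (or criteria) c."""
    if not -1.0 <= R <= 1.0:
        raise ValueError("R must lie in [-1, 1] (negative only during relaxed fit)")
    c = np.asarray(c, dtype=float)
    p_fa = ndtr(-c)
    p_hit = R + (1.0 - R) * ndtr(F - c)
    if c.ndim == 0:
        return float(p_fa), float(p_hit)
    return p_fa, p_hit


def _unpack(x, fixed_R):
    if fixed_R is None:
        R, F, c1 = x[0], x[1], x[2]
        incr = x[3:]
    else:
        R, F, c1 = fixed_R, x[0], x[1]
        incr = x[2:]
    c = c1 - np.concatenate([[0.0], np.cumsum(incr)])
    return R, F, c


def _residuals(x, fa, hit, fixed_R):
    R, F, c = _unpack(x, fixed_R)
    p_fa, p_hit = ndtr(-c), R + (1.0 - R) * ndtr(F - c)
    return np.concatenate([fa - p_fa, hit - p_hit])


_SQRT2PI = np.sqrt(2.0 * np.pi)


def _jacobian(x, fa, hit, fixed_R):
    R, F, c = _unpack(x, fixed_R)
    phi_fa = np.exp(-0.5 * c**2) / _SQRT2PI  # N(0,1) pdf at -c
    phi_hit = np.exp(-0.5 * (F - c) ** 2) / _SQRT2PI
    n_par = len(x)
    jac = np.zeros((10, n_par))
    # dc_i/dc1 = 1; dc_i/dincr_j = -1 for j <= i (criteria reparameterization)
    dc = np.zeros((5, n_par))
    off = 0 if fixed_R is not None else 1
    dc[:, off + 1] = 1.0
    for j in range(4):
        dc[j + 1 :, off + 2 + j] = -1.0
    # r_fa,i = fa_i - ndtr(-c_i)
    jac[:5] = phi_fa[:, None] * dc
    # r_hit,i = hit_i - R - (1-R) * ndtr(F - c_i)
    if fixed_R is None:
        jac[5:, 0] = -1.0 + ndtr(F - c)
    jac[5:, off] = -(1.0 - R) * phi_hit
    jac[5:] += (1.0 - R) * phi_hit[:, None] * dc
    return jac


def _criteria_init(fa: np.ndarray) -> np.ndarray:
    # probit of observed cumulative FA rates, clipped and forced decreasing
    c = -ndtri(np.clip(fa, 1e-3, 1 - 1e-3))
    for i in range(1, 5):
        c[i] = min(c[i], c[i - 1] - 0.05)
    return c


def _solve(fa, hit, starts, fixed_R, r_lo=-1.0):
    best = None
    for R0, F0 in starts:
        c0 = _criteria_init(fa)
        incr0 = np.maximum(-np.diff(c0), 0.05)
        if fixed_R is None:
            x0 = np.concatenate([[R0, F0, c0[0]], incr0])
            lo = [r_lo, 0.0, -5.0] + [1e-6] * 4
            hi = [1.0, 6.0, 5.0] + [6.0] * 4
        else:
            x0 = np.concatenate([[F0, c0[0]], incr0])
            lo = [0.0, -5.0] + [1e-6] * 4
            hi = [6.0, 5.0] + [6.0] * 4
        x0 = np.clip(x0, lo, hi)
        sol = least_squares(
            _residuals, x0, jac=_jacobian, bounds=(lo, hi),
            args=(fa, hit, fixed_R), xtol=1e-12, ftol=1e-12, gtol=1e-10,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def fit_dpsd(roc: ROCPoints) -> DPSDFit:
    """Least-squares DPSD fit to five cumulative ROC points.

    Minimizes the summed squared residuals in both the false-alarm and hit
    coordinates over (R, F, c1..c5), with criteria kept strictly ordered by
    a monotone reparameterization and multiple starting points.  A relaxed
    first pass allows R in [-1, 1]; a negative optimum triggers the R = 0
    refit.
    """
    fa = np.asarray(roc.fa, dtype=float)
    hit = np.asarray(roc.hit, dtype=float)
    degenerate = bool(np.allclose(fa, fa[0]) and np.allclose(hit, hit[0]))

    starts = [(0.0, 0.5), (0.25, 1.5), (0.5, 0.75)]
    sol = _solve(fa, hit, starts, fixed_R=None)
    R, F, c = _unpack(sol.x, None)

    refit_applied = False
    if R < 0:
        refit_applied = True
        sol = _solve(fa, hit, [(0.0, f0) for f0 in (0.25, 0.75, 1.5)], fixed_R=0.0)
        R, F, c = _unpack(sol.x, 0.0)

    return DPSDFit(
        R=float(R),
        F=float(F),
        criteria=tuple(float(v) for v in c),
        sse=float(2.0 * sol.cost),  # least_squares cost is 0.5 * SSE
        refit_applied=refit_applied,
        degenerate=degenerate,
    )
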