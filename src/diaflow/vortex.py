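"""Segmented linear surrogate model linking pTR to pulmonary-artery vortex
duration, and derivation of the t_vortex grading cutoff (rule 2).

The peak tricuspid pressure gradient follows the simplified Bernoulli
relation pTR = 4 * TR^2 (pTR in mmHg, TR in m/s). The vortex duration
t_vortex is modelled as 0 % up to a breakpoint pTR_0 and rising linearly
with a non-negative slope above it (a hockey-stick model). Fitting
profiles the breakpoint: for each candidate pTR_0 the slope has a closed
form through-the-origin least-squares solution on the excess pressures,
with the flat-segment points contributing their squared values to the
residual sum; a coarse grid over the observed pTR range is then refined
by golden-section search. The echo TR cutoff transfers to the t_vortex
scale as the model prediction at pTR(TR cutoff), with a subject-level
percentile bootstrap for its confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SegmentedModelFit",
    "tr_to_ptr",
    "predict_tvortex",
    "fit_segmented",
    "surrogate_cutoff",
]


def tr_to_ptr(tr: float) -> float:
    """Peak tricuspid pressure gradient (mmHg) from TR peak velocity (m/s)."""
    if tr < 0:
        raise ValueError(f"TR velocity must be >= 0, got {tr}")
    return 4.0 * tr * tr


@dataclass
class SegmentedModelFit:
    """Fitted hockey-stick model t_vortex(pTR).

    ``r_fit`` is the square root of the coefficient of determination.
    ``slope_clamped`` flags a fit whose unconstrained slope was negative
    and was clamped to zero. The training arrays are retained so the
    cutoff bootstrap can resample subjects.
    """

    ptr0: float                 # breakpoint, mmHg
    slope: float                # %/mmHg, >= 0
    r_fit: float                # sqrt(1 - SSE/SST), in [0, 1]
    n: int
    sse: float
    cutoff_tvortex: Optional[float] = None   # % at the TR cutoff
    cutoff_ci: Optional[tuple[float, float]] = None
    slope_clamped: bool = False
    ptr_: np.ndarray = field(default=None, repr=False)
    tvortex_: np.ndarray = field(default=None, repr=False)


def predict_tvortex(fit: SegmentedModelFit, ptr) -> float | np.ndarray:
    """Model prediction: 0 below the breakpoint, linear above, never negative."""
    ptr = np.asarray(ptr, dtype=float)
    out = fit.slope * np.maximum(0.0, ptr - fit.ptr0)
    return float(out) if out.ndim == 0 else out


def _profile_sse(x: np.ndarray, y: np.ndarray, ptr0: float) -> tuple[float, float, bool]:
    """(sse, slope, clamped) for a fixed breakpoint; slope constrained >= 0."""
    z = np.maximum(0.0, x - ptr0)
    zz = float(z @ z)
    clamped = False
    if zz == 0.0:
        slope = 0.0
    else:
        slope = float(z @ y) / zz
        if slope < 0.0:
            slope = 0.0
            clamped = True
    resid = y - slope * z
    return float(resid @ resid), slope, clamped


def _golden_section(f, a: float, b: float, tol: float) -> float:
    """Minimize a unimodal scalar function on [a, b]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def fit_segmented(ptr_values: Sequence[float], tvortex_values: Sequence[float],
                  grid_size: int = 200, refine_tol: float = 1e-9,
                  ) -> SegmentedModelFit:
    """Least-squares fit of the segmented model by breakpoint profiling.

    The breakpoint is searched on a ``grid_size``-point grid spanning the
    observed pTR range, then refined by golden-section search in the
    bracket around the best grid point. Flat-segment points contribute
    their squared t_vortex values to the objective.
    """
    x = np.asarray(ptr_values, dtype=float)
    y = np.asarray(tvortex_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pTR and t_vortex series must be 1-D and equal length")
    if x.size < 4:
        raise ValueError(f"need n >= 4 points, got {x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in fit input")
    if np.count_nonzero(y > 0) < 2:
        raise ValueError("degenerate input: fewer than 2 points with t_vortex > 0")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate input: all pTR values identical")

    lo, hi = float(x.min()), float(x.max())
    grid = np.linspace(lo, hi, grid_size)
    sse_grid = np.array([_profile_sse(x, y, b)[0] for b in grid])
    i = int(np.argmin(sse_grid))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_size - 1)]
    ptr0 = _golden_section(lambda t: _profile_sse(x, y, t)[0], a, b, refine_tol)
    # keep whichever of the refined point and the grid point is better
    if _profile_sse(x, y, ptr0)[0] > sse_grid[i]:
        ptr0 = float(grid[i])
    sse, slope, clamped = _profile_sse(x, y, ptr0)

    sst = float(((y - y.mean()) ** 2).sum())
    r_fit = math.sqrt(max(0.0, 1.0 - sse / sst)) if sst > 0 else 0.0
    return SegmentedModelFit(ptr0=float(ptr0), slope=slope, r_fit=r_fit,
                             n=int(x.size), sse=sse, slope_clamped=clamped,
                             ptr_=x.copy(), tvortex_=y.copy())


def surrogate_cutoff(fit: SegmentedModelFit, tr_cutoff: float = 2.8,
                     n_boot: int = 2000, seed: Optional[int] = None,
                     ) -> tuple[float, tuple[float, float]]:
    """t_vortex cutoff equivalent to an echo TR cutoff, with bootstrap CI.

    Point estimate: the fitted model's prediction at pTR = 4 * TR^2.
    CI: percentile interval over subject-level nonparametric bootstrap
    resamples, refitting the segmented model in each. Resamples on which
    the fit is degenerate (e.g. all resampled points on the flat segment)
    are dropped. The fit and CI are written back onto ``fit``.
    """
    if fit.ptr_ is None or fit.tvortex_ is None:
        raise ValueError("fit does not retain its training data; cannot bootstrap")
    ptr_cut = tr_to_ptr(tr_cutoff)
    point = float(predict_tvortex(fit, ptr_cut))

    rng = np.random.default_rng(seed)
    n = fit.n
    boot: list[float] = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            bfit = fit_segmented(fit.ptr_[idx], fit.tvortex_[idx],
                                 grid_size=100, refine_tol=1e-6)
        except ValueError:
            continue
        boot.append(float(predict_tvortex(bfit, ptr_cut)))
    if len(boot) >= max(10, n_boot // 10):
        lo, hi = np.percentile(boot, [2.5, 97.5])
        ci = (float(lo), float(hi))
    else:
        ci = (point, point)  # degenerate: bootstrap could not resolve a CI
    fit.cutoff_tvortex = point
    fit.cutoff_ci = ci
    return point, ci
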