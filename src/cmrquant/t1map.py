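"""Per-pixel 3-parameter inversion-recovery fitting and Look-Locker correction.

MOLLI magnitude images sample the apparent recovery
``S(TI) = |A - B exp(-TI / T1*)|``.  Because the magnitude discards the
sign of the early inverted samples, the fit restores polarity by trying
every split point k (negating the k earliest-TI samples), fitting the
signed model, and keeping the minimum-RSS candidate.  The apparent T1* is
then corrected to true T1 with the Look-Locker relation
``T1 = T1* (B/A - 1)``.

For speed, the signed fit uses variable projection: for a fixed T1* the
model is linear in (A, B), so a grid/1-D search over T1* with closed-form
(A, B) screens all polarity candidates before a bounded Levenberg-style
polish of the winner.  The selection rule (global minimum RSS over
candidates) is unchanged by the screening.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .molli import MOLLIScheme

logger = logging.getLogger(__name__)

T1_STAR_BOUNDS = (50.0, 5000.0)  # ms


@dataclass
class T1FitResult:
    """One pixel's inversion-recovery fit."""

    a_param: float
    b_param: float
    t1_star: float  # apparent T1, ms
    t1: float  # Look-Locker-corrected T1, ms
    rss: float
    valid: bool
    polarity_index: int  # how many earliest-TI samples were sign-flipped


@dataclass
class T1Map:
    """Look-Locker-corrected T1 map (ms) over a mask."""

    values: np.ndarray
    mask: np.ndarray
    valid: np.ndarray
    scheme: MOLLIScheme | None = None

    def roi_mean(self, mask: np.ndarray | None = None) -> tuple[float, int]:
        sel = (self.mask if mask is None else (self.mask & mask)) & self.valid
        n = int(sel.sum())
        if n == 0:
            raise ValueError("no valid pixels in ROI")
        return float(self.values[sel].mean()), n


def look_locker_correct(a: float, b: float, t1_star: float) -> tuple[float, bool]:
    """Correct apparent T1* to T1 = T1* (B/A - 1).

    Returns ``(t1, valid)``; the fit is flagged invalid (and t1 is NaN)
    when B/A <= 1, which has no physical inversion-recovery interpretation.
    """
    if a <= 0:
        raise ValueError("A must be positive")
    if t1_star <= 0:
        raise ValueError("T1* must be positive")
    ratio = b / a
    if ratio <= 1.0:
        return float("nan"), False
    return t1_star * (ratio - 1.0), True


def _vp_rss(tis: np.ndarray, signed: np.ndarray, t1_grid: np.ndarray):
    """Variable-projection RSS over a T1* grid: solve (A, B) in closed form.

    Returns (rss per grid point, A, B per grid point).
    """
    # model: y = A - B * e, with e = exp(-TI/T1*)
    e = np.exp(-tis[None, :] / t1_grid[:, None])  # (g, n)
    n = len(tis)
    se = e.sum(axis=1)
    see = (e * e).sum(axis=1)
    sy = signed.sum()
    sye = (signed[None, :] * e).sum(axis=1)
    det = n * see - se * se
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    a = (see * sy - se * sye) / det
    b = (se * sy - n * sye) / det  # y = a - b e  =>  normal equations
    pred = a[:, None] - b[:, None] * e
    rss = ((pred - signed[None, :]) ** 2).sum(axis=1)
    return rss, a, b


_T1_GRID = np.geomspace(T1_STAR_BOUNDS[0], T1_STAR_BOUNDS[1], 80)


def fit_ir_three_param(tis, signals) -> T1FitResult:
    """Fit ``|A - B exp(-TI/T1*)|`` to magnitude samples with polarity restoration.

    Requires at least 4 samples with distinct positive TIs.  Degenerate data
    (e.g. a constant signal) yields ``valid=False`` rather than an
    exception; fits whose T1* lands on the search bounds or whose B/A <= 1
    are likewise flagged invalid.
    """
    tis = np.asarray(tis, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if tis.shape != signals.shape or tis.ndim != 1:
        raise ValueError("tis and signals must be matching 1-D arrays")
    if len(tis) < 4:
        raise ValueError("need at least 4 samples")
    if np.any(tis <= 0) or len(np.unique(tis)) != len(tis):
        raise ValueError("TIs must be distinct and positive")

    order = np.argsort(tis)
    t_sorted = tis[order]
    s_sorted = np.abs(signals[order])
    n = len(t_sorted)

    # screen all polarity candidates with the variable-projection grid
    screened = []  # (grid rss, k, a0, b0, t1s0)
    for k in range(n):
        signed = s_sorted.copy()
        signed[:k] *= -1.0
        rss_grid, a_grid, b_grid = _vp_rss(t_sorted, signed, _T1_GRID)
        if not np.any(np.isfinite(rss_grid)):
            continue
        with np.errstate(invalid="ignore"):
            j = int(np.nanargmin(rss_grid))
        screened.append((float(rss_grid[j]), k, float(a_grid[j]), float(b_grid[j]), float(_T1_GRID[j])))
    if not screened:  # degenerate input (e.g. constant signal)
        return T1FitResult(0.0, 0.0, float("nan"), float("nan"), float("inf"), False, 0)

    # polish every candidate whose screened RSS is close to the screen winner
    # (typically 1-2 of them); minimum-RSS selection is over polished fits
    scale = max(float(s_sorted.max()), 1e-12)
    best_screen = min(c[0] for c in screened)
    cutoff = max(best_screen * 10.0, best_screen + 1e-6 * scale**2)
    lb = np.array([1e-12, 1e-12, T1_STAR_BOUNDS[0]])
    ub = np.array([np.inf, np.inf, T1_STAR_BOUNDS[1]])
    polished = []
    for rss0, k, a0, b0, t1s0 in screened:
        if rss0 > cutoff:
            continue
        signed = s_sorted.copy()
        signed[:k] *= -1.0
        x0 = np.clip(
            np.array(
                [
                    a0 if np.isfinite(a0) and a0 > 0 else scale,
                    b0 if np.isfinite(b0) and b0 > 0 else 2 * scale,
                    t1s0,
                ]
            ),
            lb,
            ub,
        )

        def resid(p, signed=signed):
            return p[0] - p[1] * np.exp(-t_sorted / p[2]) - signed

        sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=200)
        polished.append((float(np.sum(sol.fun**2)), k, sol.x))
    if not polished:
        return T1FitResult(0.0, 0.0, float("nan"), float("nan"), float("inf"), False, 0)

    rss, k_best, (a, b, t1_star) = min(polished, key=lambda c: c[0])
    at_bound = (
        t1_star <= T1_STAR_BOUNDS[0] * (1 + 1e-6) or t1_star >= T1_STAR_BOUNDS[1] * (1 - 1e-6)
    )
    if a <= 0 or at_bound:
        return T1FitResult(float(a), float(b), float(t1_star), float("nan"), rss, False, k_best)
    t1, ok = look_locker_correct(float(a), float(b), float(t1_star))
    valid = ok and not at_bound and t1 > 0
    return T1FitResult(float(a), float(b), float(t1_star), t1, rss, valid, k_best)


def compute_t1_map(stack, tis, mask, scheme: MOLLIScheme | None = None) -> T1Map:
    """Fit every masked pixel of a MOLLI stack and return the corrected T1 map.

    ``stack`` has shape ``(n_ti, rows, cols)``.  Invalid pixels carry NaN in
    the map and False in the validity plane; the invalid fraction is logged.
    """
    stack = np.asarray(stack, dtype=float)
    tis = np.asarray(tis, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stack.ndim != 3 or stack.shape[0] != len(tis):
        raise ValueError("stack frame count must match the TI list")
    if stack.shape[1:] != mask.shape:
        raise ValueError("mask shape must match the image shape")

    values = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    idx = np.argwhere(mask)
    if len(idx) == 0:
        warnings.warn("empty mask: returning an empty T1 map", stacklevel=2)
        return T1Map(values=values, mask=mask, valid=valid, scheme=scheme)
    for iy, ix in idx:
        fit = fit_ir_three_param(tis, stack[:, iy, ix])
        if fit.valid:
            values[iy, ix] = fit.t1
            valid[iy, ix] = True
    frac_bad = 1.0 - valid[mask].mean()
    logger.info("T1 fit invalid on %.1f%% of %d masked pixels", 100 * frac_bad, len(idx))
    return T1Map(values=values, mask=mask, valid=valid, scheme=scheme)
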