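"""Extracellular volume (ECV) fraction mapping from pre/post-contrast T1.

At contrast equilibrium the gadolinium-induced relaxation-rate change
``dR1 = 1/T1_post - 1/T1_pre`` is proportional to the local contrast
concentration, so the myocardial-to-blood ratio of dR1 measures the
myocardial distribution volume of the agent.  Correcting for the red-cell
volume of blood with the hematocrit gives

    ECV = (1 - Hct) * dR1_myo / dR1_blood

an imaging surrogate of diffuse interstitial fibrosis.  Values are held as
fractions internally; reports render percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def delta_r1(t1_pre: float, t1_post: float) -> float:
    """Relaxation-rate change 1/T1_post - 1/T1_pre (1/ms for T1 in ms)."""
    t1_pre = np.asarray(t1_pre, dtype=float)
    t1_post = np.asarray(t1_post, dtype=float)
    if np.any(t1_pre <= 0) or np.any(t1_post <= 0):
        raise ValueError("T1 values must be positive")
    out = 1.0 / t1_post - 1.0 / t1_pre
    return float(out) if out.ndim == 0 else out


def compute_ecv_value(
    t1_pre_myo: float,
    t1_post_myo: float,
    t1_pre_blood: float,
    t1_post_blood: float,
    hct: float,
) -> float:
    """Scalar ECV fraction from the four T1 values and the hematocrit.

    Raises when hct is outside (0, 1) or the blood dR1 is nonpositive (no
    contrast effect in blood makes the ratio meaningless).  A result
    outside [0, 1] is returned as-is; callers working pixel-wise flag such
    pixels invalid rather than clipping.
    """
    if not 0 < hct < 1:
        raise ValueError("hct must lie in (0, 1)")
    dr1_myo = delta_r1(t1_pre_myo, t1_post_myo)
    dr1_blood = delta_r1(t1_pre_blood, t1_post_blood)
    if dr1_blood <= 0:
        raise ValueError("blood delta-R1 must be positive")
    return (1.0 - hct) * dr1_myo / dr1_blood


@dataclass
class ECVMap:
    """Pixel-wise ECV fraction over the myocardial mask."""

    values: np.ndarray  # fraction; NaN where invalid or unmasked
    mask: np.ndarray
    valid: np.ndarray
    hct: float
    blood_delta_r1: float
    n_invalid: int

    def roi_mean(self, mask: np.ndarray | None = None) -> tuple[float, int]:
        return roi_mean(self.values, (self.mask if mask is None else self.mask & mask) & self.valid)


def compute_ecv_map(
    t1_pre_map: np.ndarray,
    t1_post_map: np.ndarray,
    blood_roi_pre_mean: float,
    blood_roi_post_mean: float,
    hct: float,
    myo_mask: np.ndarray,
) -> ECVMap:
    """Pixel-wise ECV over the myocardium using a single blood-pool dR1.

    The blood dR1 comes from ROI-mean pre/post T1 (an ROI mean is used
    instead of pixel-wise blood values to avoid inflow artifacts).  Pixels
    whose ECV falls outside [0, 1], or whose T1 inputs are missing/invalid,
    are flagged and excluded from ROI statistics, never clipped.
    """
    if not 0 < hct < 1:
        raise ValueError("hct must lie in (0, 1)")
    pre = np.asarray(t1_pre_map, dtype=float)
    post = np.asarray(t1_post_map, dtype=float)
    mask = np.asarray(myo_mask, dtype=bool)
    if pre.shape != post.shape or pre.shape != mask.shape:
        raise ValueError("T1 maps and mask must share a shape")
    dr1_blood = delta_r1(blood_roi_pre_mean, blood_roi_post_mean)
    if dr1_blood <= 0:
        raise ValueError("blood delta-R1 must be positive")

    values = np.full(mask.shape, np.nan)
    finite = mask & np.isfinite(pre) & np.isfinite(post) & (pre > 0) & (post > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dr1_myo = 1.0 / post[finite] - 1.0 / pre[finite]
    values[finite] = (1.0 - hct) * dr1_myo / dr1_blood
    with np.errstate(invalid="ignore"):
        valid = finite & (values >= 0) & (values <= 1)
    values[~valid] = np.nan
    n_invalid = int(mask.sum() - valid.sum())
    if n_invalid:
        logger.info("ECV invalid on %d/%d myocardial pixels", n_invalid, int(mask.sum()))
    return ECVMap(
        values=values,
        mask=mask,
        valid=valid,
        hct=hct,
        blood_delta_r1=dr1_blood,
        n_invalid=n_invalid,
    )


def roi_mean(values: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """Arithmetic mean of finite values inside a mask; returns (mean, n used)."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("values and mask must share a shape")
    sel = mask & np.isfinite(values)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("ROI contains no valid pixels")
    return float(values[sel].mean()), n
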