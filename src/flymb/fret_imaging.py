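"""Ratiometric FRET quantification by linear unmixing, plus FUNCAT ratios.

Three channels are acquired simultaneously from one excitation line: donor
(CFP), acceptor (YFP) and an autofluorescence (AF) window.  The unmixing step
corrects each signal channel against autofluorescence:

    corrected_c = c - c / AF        for c in {CFP, YFP}, per pixel,

and the sensor readout is the per-pixel ratio of the corrected channels.
The Laconic/Pyronic sensors lower FRET on analyte binding, so the comparative
sign of a ratio difference is the biological readout; the ratio orientation
(corrected CFP / corrected YFP, or its reciprocal) is a configuration choice
and the default is donor over acceptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ORIENTATIONS = ("cfp_over_yfp", "yfp_over_cfp")
DEFAULT_AF_FLOOR = 1.0


@dataclass
class FretStack:
    """Registered CFP/YFP/AF image stacks plus named ROI masks.

    Arrays may be 2-D (single plane) or 3-D (z, y, x); all three channels
    share a shape, and ROI masks are boolean with the in-plane shape.
    ``slice_index`` selects the mid-lobe plane used for quantification.
    """

    cfp: np.ndarray
    yfp: np.ndarray
    af: np.ndarray
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.cfp = np.asarray(self.cfp, dtype=float)
        self.yfp = np.asarray(self.yfp, dtype=float)
        self.af = np.asarray(self.af, dtype=float)
        if not (self.cfp.shape == self.yfp.shape == self.af.shape):
            raise ValueError("CFP, YFP and AF channels must share a shape")
        if self.cfp.ndim not in (2, 3):
            raise ValueError("channels must be 2-D or 3-D arrays")
        plane = self.cfp.shape[-2:]
        for name, mask in self.roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != plane:
                raise ValueError(f"ROI {name!r} shape {mask.shape} != plane shape {plane}")
            self.roi_masks[name] = mask
        depth = self.cfp.shape[0] if self.cfp.ndim == 3 else 1
        if not (0 <= self.slice_index < depth):
            raise ValueError("slice_index outside stack depth")


@dataclass
class FretResult:
    corr_cfp: np.ndarray
    corr_yfp: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray
    orientation: str
    roi_means: dict[str, float] = field(default_factory=dict)


def linear_unmix(stack: FretStack, af_floor: float = DEFAULT_AF_FLOOR
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Autofluorescence correction of both signal channels.

    Per pixel: ``corr_c = c - c/AF``.  Pixels with AF below ``af_floor`` are
    flagged invalid (the division is unstable there) and excluded from all
    downstream quantification.
    """
    valid = stack.af >= af_floor
    corr_cfp = np.zeros_like(stack.cfp)
    corr_yfp = np.zeros_like(stack.yfp)
    np.divide(stack.cfp, stack.af, out=corr_cfp, where=valid)
    np.divide(stack.yfp, stack.af, out=corr_yfp, where=valid)
    corr_cfp = np.where(valid, stack.cfp - corr_cfp, np.nan)
    corr_yfp = np.where(valid, stack.yfp - corr_yfp, np.nan)
    return corr_cfp, corr_yfp, valid


def fret_ratio(corr_cfp: np.ndarray, corr_yfp: np.ndarray, valid: np.ndarray,
               orientation: str = "cfp_over_yfp") -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel ratio of the corrected channels in the chosen orientation.

    Zero-denominator pixels are invalidated.  Returns ``(ratio, valid)``.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    num, den = ((corr_cfp, corr_yfp) if orientation == "cfp_over_yfp"
                else (corr_yfp, corr_cfp))
    ok = valid & (den != 0) & ~np.isnan(den)
    ratio = np.full(num.shape, np.nan)
    np.divide(num, den, out=ratio, where=ok)
    return ratio, ok


def quantify_stack(stack: FretStack, af_floor: float = DEFAULT_AF_FLOOR,
                   orientation: str = "cfp_over_yfp") -> FretResult:
    """Unmix, form the ratio map, and average every ROI at the quantification slice."""
    corr_cfp, corr_yfp, valid = linear_unmix(stack, af_floor)
    ratio, ok = fret_ratio(corr_cfp, corr_yfp, valid, orientation)
    result = FretResult(corr_cfp=corr_cfp, corr_yfp=corr_yfp, ratio=ratio,
                        valid=ok, orientation=orientation)
    for name in stack.roi_masks:
        result.roi_means[name] = roi_mean_ratio(result, stack, name)
    return result


def roi_mean_ratio(result: FretResult, stack: FretStack, roi: str,
                   slice_index: int | None = None) -> float:
    """Mean ratio over the valid pixels of one ROI at a single z slice.

    Quantification uses one plane (the mid-lobe slice) rather than a
    projection, mirroring single-slice ROI measurement practice.
    """
    if roi not in stack.roi_masks:
        raise KeyError(f"unknown ROI {roi!r}")
    z = stack.slice_index if slice_index is None else slice_index
    ratio = result.ratio[z] if result.ratio.ndim == 3 else result.ratio
    ok = result.valid[z] if result.valid.ndim == 3 else result.valid
    mask = stack.roi_masks[roi] & ok
    if not mask.any():
        raise ValueError(f"ROI {roi!r} has no valid pixels at slice {z}")
    return float(np.nanmean(ratio[mask]))


def funcat_ratio(funcat_channel: np.ndarray, reference_channel: np.ndarray,
                 roi_mask: np.ndarray, slice_index: int = 0) -> float:
    """Nascent-translation signal normalized to sensor expression.

    mean(FUNCAT over ROI) / mean(reference over ROI), measured on a single
    mid-lobe slice.  Scale-invariant: multiplying both channels by the same
    constant leaves the ratio unchanged.
    """
    fun = np.asarray(funcat_channel, dtype=float)
    ref = np.asarray(reference_channel, dtype=float)
    if fun.shape != ref.shape:
        raise ValueError("channels must share a shape")
    if fun.ndim == 3:
        fun, ref = fun[slice_index], ref[slice_index]
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != fun.shape:
        raise ValueError("ROI mask shape mismatch")
    if not mask.any():
        raise ValueError("empty ROI")
    ref_mean = float(ref[mask].mean())
    if ref_mean == 0:
        raise ZeroDivisionError("reference channel mean is zero in ROI")
    return float(fun[mask].mean()) / ref_mean
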