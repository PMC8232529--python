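"""Preprocessing pipeline: bias-field correction, isotropic resampling,
IQR intensity normalization, and central cropping/padding.

The order is fixed — correct_bias -> resample_isotropic -> iqr_normalize ->
center_crop_pad — and the whole chain is deterministic.  Masks pass only
through the geometric steps (resampling with nearest-neighbour
interpolation, cropping/padding); they are never bias-corrected or
intensity-normalized.

IQR normalization maps intensity v to v' = (v - Q1) / (Q3 - Q1), with the
quartiles taken from the central in-plane column of the volume (default
128 x 128, all slices), then clips to [-2, +6]: two IQRs below the first
quartile and five IQRs above the third (Q3 maps to 1, so 1 + 5 = 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from sklearn.base import BaseEstimator, TransformerMixin

from .imgio import SegmentationMask, Volume

CLIP_LO = -2.0
CLIP_HI = 6.0


class NormalizationError(ValueError):
    """Raised when the central column has zero IQR (constant intensities)."""


@dataclass(frozen=True)
class NormalizationParams:
    """Quartiles and clip bounds of one image's intensity normalization."""

    q1: float
    q3: float
    column_extent: int = 128
    clip_lo: float = CLIP_LO
    clip_hi: float = CLIP_HI

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _to_sitk(vol, is_mask: bool) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0))))
    img.SetSpacing(tuple(vol.spacing_mm))
    return img


def correct_bias(volume: Volume, shrink_factor: int = 2) -> Volume:
    """Reduce smooth multiplicative intensity inhomogeneity (N4).

    Delegates to the N4 bias-field correction algorithm (SimpleITK).  The
    field is estimated on a shrunken copy of the image for speed and the
    full-resolution log-bias field is then divided out — the standard N4
    usage pattern.  Requires nonnegative intensities (the correction works
    in the log domain).
    """
    if float(volume.data.min()) < 0:
        raise ValueError("bias correction requires nonnegative intensities")
    data = volume.data
    if float(data.max()) == float(data.min()):
        return volume.with_data(data.copy())  # constant image: nothing to correct
    img = _to_sitk(volume, is_mask=False)
    # strictly positive input for the log domain
    eps = max(1e-6, 1e-6 * float(data.max()))
    img = sitk.Cast(sitk.Maximum(img, eps), sitk.sitkFloat32)
    mask = sitk.Image(img.GetSize(), sitk.sitkUInt8)
    mask.CopyInformation(img)
    mask += 1
    small = sitk.Shrink(img, [shrink_factor] * 3) if shrink_factor > 1 else img
    small_mask = sitk.Shrink(mask, [shrink_factor] * 3) if shrink_factor > 1 else mask
    n4 = sitk.N4BiasFieldCorrectionImageFilter()
    n4.SetMaximumNumberOfIterations([50, 50, 50])
    n4.Execute(small, small_mask)
    log_bias = n4.GetLogBiasFieldAsImage(img)
    corrected = img / sitk.Exp(log_bias)
    out = np.transpose(sitk.GetArrayFromImage(corrected), (2, 1, 0)).astype(np.float32)
    return volume.with_data(out)


def resample_isotropic(vol_or_mask, target_spacing=(1.0, 1.0, 1.0)):
    """Resample to the target spacing, preserving physical extent.

    Output grid size per axis is round(extent_mm / target).  Images are
    interpolated linearly, binary masks by nearest neighbour (so they stay
    binary).  Already-isotropic inputs at the target spacing are returned
    unchanged.
    """
    t = np.atleast_1d(np.asarray(target_spacing, dtype=float))
    if t.size == 1:
        target = (float(t[0]),) * 3
    elif t.size == 3:
        target = tuple(float(x) for x in t)
    else:
        raise ValueError(f"target spacing must be a scalar or triple, got {target_spacing!r}")
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be positive, got {target}")
    obj = vol_or_mask
    is_mask = isinstance(obj, SegmentationMask)
    if np.allclose(obj.spacing_mm, target, rtol=1e-6):
        out_data = obj.data.copy()
        return (
            SegmentationMask(out_data, target, obj.axis_convention)
            if is_mask
            else Volume(out_data, target, obj.axis_convention)
        )
    new_size = [
        int(np.floor(n * s / t + 0.5))
        for n, s, t in zip(obj.shape, obj.spacing_mm, target)
    ]
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(obj.data, (2, 1, 0))))
    img.SetSpacing(tuple(obj.spacing_mm))
    interp = sitk.sitkNearestNeighbor if is_mask else sitk.sitkLinear
    res = sitk.Resample(
        img,
        [int(n) for n in new_size],
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        target,
        img.GetDirection(),
        0.0,
        sitk.sitkFloat32,
    )
    out = np.transpose(sitk.GetArrayFromImage(res), (2, 1, 0)).astype(np.float32)
    if is_mask:
        return SegmentationMask(out, target, obj.axis_convention)
    return Volume(out, target, obj.axis_convention)


def _central_column(data: np.ndarray, extent: int) -> np.ndarray:
    """In-plane centred window of extent^2 over all slices (shrinks to grid)."""
    nx, ny, _ = data.shape
    ex, ey = min(extent, nx), min(extent, ny)
    x0 = (nx - ex) // 2
    y0 = (ny - ey) // 2
    return data[x0 : x0 + ex, y0 : y0 + ey, :]


def iqr_normalize(volume: Volume, column_extent: int = 128) -> tuple[Volume, NormalizationParams]:
    """Normalize to the image-level IQR of the central column; clip to [-2, 6]."""
    col = _central_column(volume.data, column_extent).astype(np.float64)
    q1, q3 = np.quantile(col, [0.25, 0.75])  # linear-interpolation convention
    iqr = q3 - q1
    if iqr <= 0:
        raise NormalizationError(
            f"central {column_extent}x{column_extent} column has zero IQR (q1=q3={q1})"
        )
    out = np.clip((volume.data.astype(np.float64) - q1) / iqr, CLIP_LO, CLIP_HI)
    params = NormalizationParams(q1=float(q1), q3=float(q3), column_extent=column_extent)
    return volume.with_data(out.astype(np.float32)), params


def center_crop_pad(vol_or_mask, inplane: int = 128, slices: int = 136, pad_value=None):
    """Crop or pad to an exact (inplane, inplane, slices) grid, centred.

    Odd crop/pad remainders put the extra voxel on the high-index side, so
    the centre voxel of the input always maps to the centre of the output.
    ``pad_value`` defaults to the post-normalization minimum (-2) for
    images and 0 for masks.
    """
    obj = vol_or_mask
    is_mask = isinstance(obj, SegmentationMask)
    if pad_value is None:
        pad_value = 0.0 if is_mask else CLIP_LO
    targets = (int(inplane), int(inplane), int(slices))
    data = obj.data
    for axis, tgt in enumerate(targets):
        n = data.shape[axis]
        if n > tgt:
            start = (n - tgt) // 2
            data = np.take(data, np.arange(start, start + tgt), axis=axis)
        elif n < tgt:
            lo = (tgt - n) // 2
            hi = tgt - n - lo
            pads = [(0, 0)] * 3
            pads[axis] = (lo, hi)
            data = np.pad(data, pads, constant_values=pad_value)
    data = np.ascontiguousarray(data)
    if is_mask:
        return SegmentationMask(data, obj.spacing_mm, obj.axis_convention)
    return Volume(data, obj.spacing_mm, obj.axis_convention)


def preprocess_case(
    volume: Volume,
    mask: SegmentationMask | None = None,
    target_spacing=(1.0, 1.0, 1.0),
    inplane: int = 128,
    slices: int = 136,
    column_extent: int = 128,
    bias_correct: bool = True,
):
    """Full pipeline on a (volume, mask) pair; the mask sees only geometry.

    Returns (volume', mask' or None, NormalizationParams).
    """
    vol = correct_bias(volume) if bias_correct else volume
    vol = resample_isotropic(vol, target_spacing)
    vol, params = iqr_normalize(vol, column_extent=column_extent)
    vol = center_crop_pad(vol, inplane=inplane, slices=slices)
    out_mask = None
    if mask is not None:
        out_mask = resample_isotropic(mask, target_spacing)
        out_mask = center_crop_pad(out_mask, inplane=inplane, slices=slices)
    return vol, out_mask, params


# ---------------------------------------------------------------------------
# Transformer-style wrappers (compose with sklearn pipelines)
# ---------------------------------------------------------------------------

class _StatelessTransformer(BaseEstimator, TransformerMixin):
    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return [self._apply(x) for x in X]


class BiasFieldCorrector(_StatelessTransformer):
    """N4-style bias correction over a list of Volumes."""

    def __init__(self, shrink_factor: int = 2):
        self.shrink_factor = shrink_factor

    def _apply(self, vol):
        return correct_bias(vol, shrink_factor=self.shrink_factor)


class IsotropicResampler(_StatelessTransformer):
    def __init__(self, target_spacing=(1.0, 1.0, 1.0)):
        self.target_spacing = target_spacing

    def _apply(self, obj):
        return resample_isotropic(obj, self.target_spacing)


class IQRNormalizer(_StatelessTransformer):
    def __init__(self, column_extent: int = 128):
        self.column_extent = column_extent

    def _apply(self, vol):
        out, _ = iqr_normalize(vol, column_extent=self.column_extent)
        return out


class CenterCropPad(_StatelessTransformer):
    def __init__(self, inplane: int = 128, slices: int = 136, pad_value=None):
        self.inplane = inplane
        self.slices = slices
        self.pad_value = pad_value

    def _apply(self, obj):
        return center_crop_pad(obj, self.inplane, self.slices, self.pad_value)
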