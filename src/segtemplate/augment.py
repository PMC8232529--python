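"""Real-time per-epoch augmentation.

Three transforms, applied in a fixed order with one shared geometry for
image and mask: random elastic deformation, random rotation (in-plane
angle uniform on [-pi/8, pi/8] about the slice axis, through-plane tilt
uniform on [-pi/4, pi/4] about the x axis), and mirroring across the y
axis with probability ``mirror_prob``.  The image is interpolated
linearly, the mask by nearest neighbour (it stays binary).  After the
transforms the sample is cropped to the central in-plane column.

Each transform draws from its own seed-derived random stream, so
disabling one transform does not change the draws of the others and every
augmented sample is a pure function of (input, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imgio import SegmentationMask, Volume, derive_seed
from .preprocess import CLIP_LO


class AugmentationError(RuntimeError):
    """Raised when repeated augmentation attempts empty the mask."""


@dataclass(frozen=True)
class AugmentConfig:
    """Parameters of the three augmentation transforms.

    ``elastic_sigma_mm`` controls the smoothness of the random displacement
    field, ``elastic_alpha_mm`` its RMS magnitude; rotation bounds are in
    radians.  ``crop_inplane`` is the in-plane column extent kept after the
    transforms (no-op when the sample is already that small).
    """

    elastic_sigma_mm: float = 8.0
    elastic_alpha_mm: float = 10.0
    rot_inplane_max: float = float(np.pi / 8)
    rot_throughplane_max: float = float(np.pi / 4)
    mirror_prob: float = 0.5
    crop_inplane: int = 128
    elastic: bool = True
    rotate: bool = True
    mirror: bool = True
    fill_value: float = CLIP_LO

    def __post_init__(self):
        if not 0 <= self.mirror_prob <= 1:
            raise ValueError(f"mirror_prob must be in [0,1], got {self.mirror_prob}")
        for name in ("elastic_sigma_mm", "elastic_alpha_mm", "rot_inplane_max",
                     "rot_throughplane_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def disabled() -> AugmentConfig:
    """Config with every transform off (identity up to the central crop)."""
    return AugmentConfig(elastic=False, rotate=False, mirror=False)


def draw_parameters(config: AugmentConfig, seed: int) -> dict:
    """Sample the random transform parameters for one augmentation call."""
    rng_rot = np.random.default_rng(derive_seed(seed, "rotate"))
    rng_mir = np.random.default_rng(derive_seed(seed, "mirror"))
    return {
        "elastic_seed": derive_seed(seed, "elastic"),
        "angle_inplane": float(rng_rot.uniform(-config.rot_inplane_max, config.rot_inplane_max)),
        "angle_throughplane": float(
            rng_rot.uniform(-config.rot_throughplane_max, config.rot_throughplane_max)
        ),
        "mirror": bool(rng_mir.random() < config.mirror_prob),
    }


def _elastic_coords(shape, spacing, sigma_mm, alpha_mm, seed):
    rng = np.random.default_rng(seed)
    coords = np.indices(shape).astype(np.float64)
    for axis in range(3):
        noise = rng.standard_normal(shape)
        sigma_vox = [max(sigma_mm / s, 1e-6) for s in spacing]
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
        rms = np.sqrt((smooth**2).mean())
        if rms > 0:
            smooth *= (alpha_mm / spacing[axis]) / rms  # displacement in voxels
        coords[axis] += smooth
    return coords


def _rotation_matrix(angle_inplane: float, angle_through: float) -> np.ndarray:
    ci, si = np.cos(angle_inplane), np.sin(angle_inplane)
    ct, st = np.cos(angle_through), np.sin(angle_through)
    rz = np.array([[ci, -si, 0.0], [si, ci, 0.0], [0.0, 0.0, 1.0]])  # about slice axis
    rx = np.array([[1.0, 0.0, 0.0], [0.0, ct, -st], [0.0, st, ct]])  # about x (tilt)
    return rz @ rx


def _compose_coords(shape, spacing, params, config: AugmentConfig):
    """Sampling coordinates of the composed elastic+rotation transform.

    The two geometric transforms are composed into one coordinate map so
    image and mask are resampled exactly once (a single interpolation
    keeps the mask boundary crisper than chaining resamples).  With both
    transforms off, returns None (identity).
    """
    do_elastic = config.elastic and config.elastic_alpha_mm > 0
    if not do_elastic and not config.rotate:
        return None
    if config.rotate:
        rot = _rotation_matrix(params["angle_inplane"], params["angle_throughplane"])
        center = (np.asarray(shape) - 1) / 2.0
        grid = np.indices(shape).reshape(3, -1).astype(np.float64)
        # output coord v samples input coord R^-1 v (about the centre)
        base = (rot.T @ (grid - center[:, None])) + center[:, None]
        base = base.reshape((3,) + tuple(shape))
    else:
        base = np.indices(shape).astype(np.float64)
    if do_elastic:
        disp = _elastic_coords(
            shape, spacing, config.elastic_sigma_mm, config.elastic_alpha_mm,
            params["elastic_seed"],
        ) - np.indices(shape)
        if config.rotate:
            # displacement field evaluated at the rotated coordinates
            disp = np.stack(
                [ndimage.map_coordinates(d, base, order=1, mode="nearest") for d in disp]
            )
        base = base + disp
    return base


def _apply_geometry(data, coords, params, config: AugmentConfig, order, cval):
    if coords is None:
        out = data.astype(np.float64)
    else:
        out = ndimage.map_coordinates(
            data.astype(np.float64), coords, order=order, cval=cval, mode="constant"
        )
    if config.mirror and params["mirror"]:
        out = out[:, ::-1, :]
    return np.ascontiguousarray(out)


def _crop_inplane(data, extent, pad_value):
    ex = min(extent, data.shape[0]), min(extent, data.shape[1])
    x0 = (data.shape[0] - ex[0]) // 2
    y0 = (data.shape[1] - ex[1]) // 2
    return data[x0 : x0 + ex[0], y0 : y0 + ex[1], :]


def augment_sample(
    volume: Volume, mask: SegmentationMask, config: AugmentConfig | None, seed: int
) -> tuple[Volume, SegmentationMask]:
    """One augmented (volume, mask) pair; deterministic given seed.

    Image and mask receive the identical geometric transform.  If the
    transform empties the mask, the draw is retried with a derived seed
    (at most 5 attempts) before raising :class:`AugmentationError`.
    """
    if config is None:
        config = disabled()
    if volume.shape != mask.shape:
        raise ValueError(f"volume {volume.shape} and mask {mask.shape} are not aligned")
    spacing = volume.spacing_mm
    for attempt in range(5):
        params = draw_parameters(config, derive_seed(seed, attempt) if attempt else seed)
        coords = _compose_coords(volume.shape, spacing, params, config)
        img = _apply_geometry(volume.data, coords, params, config, order=1,
                              cval=config.fill_value)
        msk = _apply_geometry(mask.data, coords, params, config, order=0, cval=0.0)
        img = _crop_inplane(img, config.crop_inplane, config.fill_value)
        msk = _crop_inplane(msk, config.crop_inplane, 0.0)
        if msk.any():
            return (
                Volume(img.astype(np.float32), spacing, volume.axis_convention),
                SegmentationMask((msk > 0.5).astype(np.float32), spacing,
                                 mask.axis_convention),
            )
    raise AugmentationError(f"augmentation emptied the mask after 5 attempts (seed {seed})")


def epoch_stream(cases, config: AugmentConfig | None, epoch_index: int, master_seed: int):
    """Yield one augmented sample per case for one epoch.

    ``cases`` is a sequence of (case_id, Volume, SegmentationMask).  The
    per-sample seed is derived from (master_seed, epoch_index, case_id),
    so the stream is reproducible and independent of case order.  With
    ``config=None`` the raw samples are yielded (deterministic training).
    """
    cases = list(cases)
    if not cases:
        raise ValueError("empty case list")
    for case_id, vol, mask in cases:
        if config is None:
            yield case_id, vol, mask
        else:
            seed = derive_seed(master_seed, epoch_index, case_id)
            vol2, mask2 = augment_sample(vol, mask, config, seed)
            yield case_id, vol2, mask2
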