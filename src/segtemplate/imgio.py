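"""Volume/mask containers, NIfTI and MetaImage I/O, and experiment configuration.

In-memory convention
--------------------
Arrays are indexed ``(x, y, slice)``: axis 2 is the through-plane (slice)
axis.  Files whose headers declare a different axis-aligned orientation are
permuted to this order on read.  Which end of the slice axis is the organ
apex is tracked explicitly (``AxisConvention``) because the subvolume split
(apex / midgland / base) depends on it; the flag is encoded in the file
header as the sign of the through-plane direction cosine, so it survives a
save/load round trip.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import SimpleITK as sitk
import yaml


class ImageIOError(RuntimeError):
    """Raised for unreadable files, metadata corruption, or format violations."""


class ConfigError(ValueError):
    """Raised when an experiment configuration is invalid; names the offending key."""


@dataclass(frozen=True)
class AxisConvention:
    """Orientation bookkeeping for a canonical ``(x, y, slice)`` array.

    Parameters
    ----------
    apex_low : bool
        True if the organ apex is at slice index 0, False if at the last
        slice.  The default matches the package-wide convention; datasets
        with the opposite ordering set this per-volume (or via config).
    """

    apex_low: bool = True

    @property
    def slice_axis(self) -> int:
        return 2


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm.

    ``data`` is float32, indexed (x, y, slice); ``spacing_mm`` is the voxel
    edge length per axis in the same order.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    axis_convention: AxisConvention = field(default_factory=AxisConvention)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ImageIOError(f"Volume requires 3D data, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ImageIOError(f"spacing must be three positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ImageIOError("Volume data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, spacing_mm=None) -> "Volume":
        return Volume(data, spacing_mm or self.spacing_mm, self.axis_convention)


@dataclass
class SegmentationMask:
    """A per-voxel label map aligned to a :class:`Volume` grid.

    ``data`` is either binary {0,1} or a soft probability map in [0,1];
    both are stored as float32.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    axis_convention: AxisConvention = field(default_factory=AxisConvention)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ImageIOError(f"mask requires 3D data, got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ImageIOError(f"spacing must be positive, got {self.spacing_mm}")
        lo, hi = float(self.data.min(initial=0)), float(self.data.max(initial=0))
        if lo < 0 or hi > 1:
            raise ImageIOError(f"mask values must lie in [0,1], got range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0.0, 1.0)).all())

    def binarized(self, threshold: float = 0.5) -> "SegmentationMask":
        return SegmentationMask(
            (self.data > threshold).astype(np.float32), self.spacing_mm, self.axis_convention
        )

    def with_data(self, data: np.ndarray) -> "SegmentationMask":
        return SegmentationMask(data, self.spacing_mm, self.axis_convention)


_EXTENSIONS = (".nii", ".nii.gz", ".mhd")


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _EXTENSIONS):
        raise ImageIOError(
            f"unsupported extension for '{path}': expected one of {_EXTENSIONS}"
        )


def _to_sitk(data: np.ndarray, spacing_mm, apex_low: bool) -> sitk.Image:
    # sitk expects (z, y, x) arrays and (x, y, z) spacing
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing_mm))
    zs = 1.0 if apex_low else -1.0
    img.SetDirection((1.0, 0, 0, 0, 1.0, 0, 0, 0, zs))
    return img


def _from_sitk(img: sitk.Image, path: Path) -> tuple[np.ndarray, tuple, AxisConvention]:
    if img.GetDimension() != 3:
        raise ImageIOError(f"'{path}': expected a 3D image, got {img.GetDimension()}D")
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    # accept axis-aligned orientations only: permutation matrix up to signs
    perm = np.argmax(np.abs(direction), axis=0)
    if sorted(perm) != [0, 1, 2] or not np.allclose(
        np.abs(direction)[perm, range(3)], 1.0, atol=1e-6
    ):
        raise ImageIOError(f"'{path}': non-axis-aligned direction matrix is unsupported")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.transpose(arr, (2, 1, 0)).astype(np.float32)
    spacing = tuple(float(s) for s in img.GetSpacing())
    # permute file axes to canonical (x, y, slice)
    if tuple(perm) != (0, 1, 2):
        inv = np.argsort(perm)
        data = np.transpose(data, tuple(inv))
        spacing = tuple(spacing[i] for i in inv)
    apex_low = direction[2, int(np.argsort(perm)[2])] >= 0
    return data, spacing, AxisConvention(apex_low=bool(apex_low))


def read_volume(path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mhd) volume."""
    path = Path(path)
    _check_extension(path)
    if not path.exists():
        raise ImageIOError(f"no such file: '{path}'")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # sitk wraps all read failures in RuntimeError
        raise ImageIOError(f"failed to read '{path}': {exc}") from exc
    data, spacing, conv = _from_sitk(img, path)
    return Volume(data, spacing, conv)


def write_volume(volume: Volume, path) -> None:
    """Write a volume; format chosen by extension (.nii/.nii.gz/.mhd)."""
    path = Path(path)
    _check_extension(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = _to_sitk(volume.data, volume.spacing_mm, volume.axis_convention.apex_low)
    sitk.WriteImage(img, str(path))


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a binary mask as unsigned 8-bit labels (probabilities are in-memory only)."""
    if not mask.is_binary:
        raise ImageIOError("only binary masks are written to file; binarize soft masks first")
    path = Path(path)
    _check_extension(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = _to_sitk(mask.data.astype(np.uint8), mask.spacing_mm, mask.axis_convention.apex_low)
    sitk.WriteImage(sitk.Cast(img, sitk.sitkUInt8), str(path))


def read_mask(path, reference: Volume) -> SegmentationMask:
    """Read a label file and align it with ``reference``.

    Integer-labeled files with a single foreground label are binarized by
    ``x > 0.5``; files with more than one foreground label are rejected.
    """
    path = Path(path)
    _check_extension(path)
    if not path.exists():
        raise ImageIOError(f"no such file: '{path}'")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise ImageIOError(f"failed to read '{path}': {exc}") from exc
    data, spacing, conv = _from_sitk(img, path)
    if data.shape != reference.shape:
        raise ImageIOError(
            f"'{path}': mask grid {data.shape} does not match reference {reference.shape}"
        )
    if not np.allclose(spacing, reference.spacing_mm, rtol=1e-4):
        raise ImageIOError(
            f"'{path}': mask spacing {spacing} does not match reference {reference.spacing_mm}"
        )
    labels = np.unique(data)
    foreground = labels[labels > 0.5]
    if len(foreground) > 1:
        raise ImageIOError(f"'{path}': multi-label file (labels {sorted(labels)}) rejected")
    return SegmentationMask(
        (data > 0.5).astype(np.float32), reference.spacing_mm, reference.axis_convention
    )


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------

#: defaults mirror the study protocol: five CV folds, Adam at 1e-5,
#: 100-epoch refinement budget
_CONFIG_DEFAULTS: dict[str, Any] = {
    "folds": 5,
    "group_by_patient": True,
    "learning_rate": 1e-5,
    "epochs": 100,
    "refine_epochs": 100,
    "ood_epochs": 150,
    "batch_seed": 0,
    "base_features": 8,
    "input_shape": [128, 128, 136],
    "augment": {
        "elastic_sigma_mm": 8.0,
        "elastic_alpha_mm": 10.0,
        "rot_inplane_max": float(np.pi / 8),
        "rot_throughplane_max": float(np.pi / 4),
        "mirror_prob": 0.5,
        "enabled": True,
    },
    "domains": {},
    "dataset_sizes": {},
    "ablation_fractions": [0.05, 0.10, 0.15, 0.20, 0.40, 0.60, 0.80, 1.0],
}

_REQUIRED_POSITIVE = {"folds", "learning_rate", "epochs", "refine_epochs", "ood_epochs"}


def _merge_config(defaults: Mapping, user: Mapping, prefix: str = "") -> dict:
    out = dict(defaults)
    for key, value in user.items():
        full = f"{prefix}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown configuration key '{full}'")
        if isinstance(defaults[key], Mapping) and key not in ("domains", "dataset_sizes"):
            if not isinstance(value, Mapping):
                raise ConfigError(f"'{full}' must be a mapping")
            out[key] = _merge_config(defaults[key], value, prefix=f"{full}.")
        else:
            out[key] = value
    return out


def load_experiment_config(path_or_dict) -> dict:
    """Load and validate an experiment configuration.

    Accepts a YAML path or an already-parsed mapping.  Missing keys receive
    protocol defaults (5 folds, learning rate 1e-5, 100 refinement epochs);
    unknown keys raise :class:`ConfigError`.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    cfg = _merge_config(_CONFIG_DEFAULTS, raw)
    for key in _REQUIRED_POSITIVE:
        if not (isinstance(cfg[key], (int, float)) and cfg[key] > 0):
            raise ConfigError(f"'{key}' must be positive, got {cfg[key]!r}")
    if int(cfg["folds"]) != cfg["folds"]:
        raise ConfigError(f"'folds' must be an integer, got {cfg['folds']!r}")
    ap = cfg["augment"]
    if not 0 <= ap["mirror_prob"] <= 1:
        raise ConfigError(f"'augment.mirror_prob' must be in [0,1], got {ap['mirror_prob']}")
    for key in ("elastic_sigma_mm", "elastic_alpha_mm", "rot_inplane_max", "rot_throughplane_max"):
        if ap[key] < 0:
            raise ConfigError(f"'augment.{key}' must be nonnegative, got {ap[key]}")
    for frac in cfg["ablation_fractions"]:
        if not 0 < frac <= 1:
            raise ConfigError(f"ablation fraction {frac} outside (0, 1]")
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration, for checkpoint provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def derive_seed(*parts) -> int:
    """Deterministic child seed from heterogeneous parts (always < 2**31).

    Used everywhere a per-case / per-epoch seed is derived from a master
    seed, so results are independent of iteration order.
    """
    blob = "\x1f".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.blake2b(blob, digest_size=4).digest(), "big") % (2**31)


def write_results_csv(records, path) -> None:
    """Write a list of dataclass records (e.g. MetricRecord) to CSV."""
    import pandas as pd

    rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in records]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_results_csv(path):
    import pandas as pd

    return pd.read_csv(path)
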