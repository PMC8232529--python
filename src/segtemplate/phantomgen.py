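"""Synthetic 3D MRI-like phantoms with ground-truth and degraded annotations.

The generator emulates the statistical structure a multi-site organ
segmentation study has to cope with:

* an organ of smoothly lobed ellipsoidal shape (low-order spherical-harmonic
  radial modulation) on a constant background;
* a smooth multiplicative bias field (coil inhomogeneity), a linear
  intensity gradient along one axis (coil falloff), and additive Gaussian
  noise;
* "clinical-style" annotations produced by displacing the true boundary
  with a smooth random field of prescribed RMS amplitude in mm — rough
  contours of the kind produced in routine workflows, as opposed to the
  clean research-grade reference masks;
* domains that differ in contrast, noise, voxel anisotropy and annotation
  roughness, plus a "distractor" task (off-centre multi-lobed target) that
  stands in for an out-of-domain pretraining dataset.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage
from scipy.special import sph_harm_y

from .imgio import AxisConvention, SegmentationMask, Volume, derive_seed


class GenerationError(RuntimeError):
    """Raised when a phantom or annotation degenerates (too small / empty)."""


@dataclass(frozen=True)
class DomainSpec:
    """Parameterization of one synthetic imaging domain."""

    name: str
    grid_shape: tuple[int, int, int] = (48, 48, 36)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    organ_radius_frac: float = 0.3
    shape_irregularity: float = 0.15
    organ_intensity: float = 1.0
    background_intensity: float = 0.2
    contrast_gradient: float = 0.0
    noise_sd: float = 0.05
    bias_strength: float = 0.2
    annotation_roughness_mm: float = 0.0
    task: str = "organ"

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three extents >= 8, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if not 0 < self.organ_radius_frac < 0.5:
            raise ValueError(f"organ_radius_frac must be in (0, 0.5), got {self.organ_radius_frac}")
        if self.noise_sd < 0 or self.shape_irregularity < 0:
            raise ValueError("noise_sd and shape_irregularity must be nonnegative")
        if not 0 <= self.bias_strength <= 0.9:
            raise ValueError(f"bias_strength must be in [0, 0.9], got {self.bias_strength}")
        if self.annotation_roughness_mm < 0:
            raise ValueError("annotation_roughness_mm must be nonnegative")
        if self.task not in ("organ", "distractor"):
            raise ValueError(f"task must be 'organ' or 'distractor', got {self.task!r}")
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))


@dataclass
class PhantomCase:
    """One synthetic study: image, clean truth mask, degraded clinical mask."""

    case_id: str
    patient_id: str
    volume: Volume
    truth_mask: SegmentationMask
    clinical_mask: SegmentationMask
    domain: str
    seed: int


def make_bias_field(grid_shape, spacing_mm, bias_strength: float, seed: int) -> Volume:
    """Smooth multiplicative bias field with values in [1-s, 1+s], mean ~ 1.

    The field is the exponential of a random order-3 polynomial in
    normalized coordinates — the low-frequency multiplicative model that
    bias-correction algorithms assume — rescaled to the requested range and
    renormalized to unit spatial mean.
    """
    if not 0 <= bias_strength <= 0.9:
        raise ValueError(f"bias_strength must be in [0, 0.9], got {bias_strength}")
    grid_shape = tuple(int(n) for n in grid_shape)
    if bias_strength == 0:
        return Volume(np.ones(grid_shape, dtype=np.float32), spacing_mm)
    rng = np.random.default_rng(seed)
    axes = [np.linspace(-1.0, 1.0, n) for n in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    poly = np.zeros(grid_shape)
    for i in range(4):
        for j in range(4 - i):
            for k in range(4 - i - j):
                if i == j == k == 0:
                    continue  # constant term has no spatial effect
                poly += rng.normal() * xx**i * yy**j * zz**k
    poly -= poly.mean()
    amp = np.abs(poly).max()
    if amp > 0:
        poly *= np.log1p(bias_strength) / amp
    fld = np.exp(poly)
    fld /= fld.mean()
    fld = np.clip(fld, 1.0 - bias_strength, 1.0 + bias_strength)
    return Volume(fld.astype(np.float32), spacing_mm)


def _real_sph_harm(ell: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real-valued spherical harmonic (polar angle theta, azimuth phi)."""
    y = sph_harm_y(ell, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * y.real
    if m < 0:
        return np.sqrt(2.0) * y.imag
    return y.real


def _radial_modulation(theta, phi, irregularity: float, rng, max_degree: int = 4):
    """1 + smooth lobed perturbation of the unit radius (RMS ~ irregularity)."""
    if irregularity == 0:
        return np.ones_like(theta)
    pert = np.zeros_like(theta)
    for ell in range(1, max_degree + 1):
        for m in range(-ell, ell + 1):
            pert += rng.normal() * _real_sph_harm(ell, m, theta, phi)
    rms = np.sqrt((pert**2).mean())
    if rms > 0:
        pert *= irregularity / rms
    return 1.0 + np.clip(pert, -0.6, 0.6)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _organ_mask(domain: DomainSpec, rng) -> np.ndarray:
    shape = np.asarray(domain.grid_shape, dtype=float)
    idx = np.indices(domain.grid_shape).astype(float)
    if domain.task == "organ":
        center = shape / 2.0 + rng.uniform(-0.05, 0.05, 3) * shape
        radii = domain.organ_radius_frac * shape
        u = (idx - center[:, None, None, None]) / radii[:, None, None, None]
        r = np.sqrt((u**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.where(r > 0, u[2] / np.maximum(r, 1e-12), 1.0), -1, 1))
            phi = np.arctan2(u[1], u[0])
        bound = _radial_modulation(theta, phi, domain.shape_irregularity, rng)
        mask = r <= bound
    else:
        # distractor: off-centre main lobe plus two attached satellite lobes
        center = shape / 2.0 + rng.uniform(0.1, 0.2, 3) * shape * rng.choice([-1, 1], 3)
        radii = 0.6 * domain.organ_radius_frac * shape
        u = (idx - center[:, None, None, None]) / radii[:, None, None, None]
        mask = (u**2).sum(axis=0) <= 1.0
        for _ in range(2):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            lobe_center = center + direction * radii * 0.9
            lobe_radii = radii * rng.uniform(0.5, 0.8)
            v = (idx - lobe_center[:, None, None, None]) / lobe_radii[:, None, None, None]
            mask |= (v**2).sum(axis=0) <= 1.0
    return _largest_component(mask)


def generate_phantom(domain: DomainSpec, seed: int) -> tuple[Volume, SegmentationMask]:
    """Render one phantom volume and its clean binary truth mask."""
    rng = np.random.default_rng(seed)
    mask = _organ_mask(domain, rng)
    if mask.sum() < 10:
        raise GenerationError(
            f"organ degenerated to {int(mask.sum())} voxels in domain '{domain.name}'"
        )
    img = domain.background_intensity + (
        domain.organ_intensity - domain.background_intensity
    ) * mask.astype(np.float64)
    if domain.contrast_gradient != 0:
        ny = domain.grid_shape[1]
        ramp = 1.0 + domain.contrast_gradient * (np.arange(ny) / max(ny - 1, 1) - 0.5)
        img *= ramp[None, :, None]
    bias = make_bias_field(
        domain.grid_shape, domain.spacing_mm, domain.bias_strength, derive_seed(seed, "bias")
    )
    img *= bias.data.astype(np.float64)
    if domain.noise_sd > 0:
        img += rng.normal(0.0, domain.noise_sd, domain.grid_shape)
    # MR magnitude images are nonnegative; clip the Gaussian-noise tail
    img = np.clip(img, 0.0, None)
    conv = AxisConvention(apex_low=True)
    return (
        Volume(img.astype(np.float32), domain.spacing_mm, conv),
        SegmentationMask(mask.astype(np.float32), domain.spacing_mm, conv),
    )


def degrade_annotation(
    truth_mask: SegmentationMask, spacing_mm, roughness_mm: float, seed: int
) -> SegmentationMask:
    """Simulate a rough clinical contour by jittering the boundary.

    The true boundary is displaced along its normal by a smooth random
    field with RMS amplitude ``roughness_mm``: the signed Euclidean
    distance map of the truth (in mm) is thresholded at the displacement
    field.  The field is generated per slice (strong in-plane smoothing)
    with mild inter-slice decorrelation, mimicking slice-wise manual
    contouring.  ``roughness_mm = 0`` returns the input unchanged.
    """
    if roughness_mm < 0:
        raise ValueError(f"roughness_mm must be nonnegative, got {roughness_mm}")
    m = truth_mask.data > 0.5
    if not m.any():
        raise GenerationError("cannot degrade an empty mask")
    if roughness_mm == 0:
        return SegmentationMask(
            truth_mask.data.copy(), truth_mask.spacing_mm, truth_mask.axis_convention
        )
    spacing = tuple(float(s) for s in spacing_mm)
    rng = np.random.default_rng(seed)
    d_out = ndimage.distance_transform_edt(~m, sampling=spacing)
    d_in = ndimage.distance_transform_edt(m, sampling=spacing)
    signed = d_in - d_out  # positive inside, mm
    noise = rng.standard_normal(m.shape)
    sigma_vox = (6.0 / spacing[0], 6.0 / spacing[1], 1.0 / spacing[2])
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    rms = np.sqrt((smooth**2).mean())
    disp = smooth * (roughness_mm / max(rms, 1e-12))
    out = signed + disp > 0
    out = _largest_component(out)
    if not out.any():
        raise GenerationError("annotation degradation emptied the mask")
    return SegmentationMask(
        out.astype(np.float32), truth_mask.spacing_mm, truth_mask.axis_convention
    )


def generate_case(domain: DomainSpec, case_id: str, patient_id: str, seed: int) -> PhantomCase:
    vol, truth = generate_phantom(domain, seed)
    clinical = degrade_annotation(
        truth, domain.spacing_mm, domain.annotation_roughness_mm, derive_seed(seed, "annot")
    )
    return PhantomCase(case_id, patient_id, vol, truth, clinical, domain.name, seed)


def generate_dataset(
    domain: DomainSpec, n_cases: int, n_patients: int, seed: int
) -> list[PhantomCase]:
    """Generate a dataset of cases; several cases may share a patient.

    Case ``i`` belongs to patient ``i mod n_patients``, so whenever
    n_cases > n_patients some patients contribute repeat studies (the
    longitudinal structure grouped cross-validation must respect).
    Per-case seeds derive deterministically from the master seed.
    """
    if n_patients < 1 or n_cases < n_patients:
        raise ValueError(f"need n_cases >= n_patients >= 1, got {n_cases}, {n_patients}")
    cases = []
    for i in range(n_cases):
        cases.append(
            generate_case(
                domain,
                case_id=f"{domain.name}-{i:04d}",
                patient_id=f"{domain.name}-p{i % n_patients:04d}",
                seed=derive_seed(seed, domain.name, i),
            )
        )
    return cases


def load_domain_presets(path=None) -> dict[str, DomainSpec]:
    """Named domain presets from YAML (the shipped library by default)."""
    if path is None:
        text = resources.files("segtemplate").joinpath("data/domains.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {}
    for name, params in raw.items():
        params = dict(params)
        for key in ("grid_shape", "spacing_mm"):
            if key in params:
                params[key] = tuple(params[key])
        out[name] = DomainSpec(name=name, **params)
    return out


def scaled_domain(spec: DomainSpec, grid_shape, **overrides) -> DomainSpec:
    """A copy of ``spec`` on a different grid (used by desk-scale presets)."""
    return replace(spec, grid_shape=tuple(int(n) for n in grid_shape), **overrides)
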