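"""Synthetic B-mode-like phantom generation.

Clinical breast ultrasound images cannot be redistributed, so this module
manufactures 2-D grayscale images that carry the acoustic features a
segmentation pipeline must cope with: a hypoechoic (darker) lesion with a
smooth-to-spiculated margin, fully developed multiplicative speckle, optional
posterior acoustic shadowing beneath the lesion, and an optional hyperechoic
halo around it.  Every phantom comes with its exact binary ground-truth mask,
which makes all downstream stages (preprocessing, training, voting, level-set
evolution, metrics) testable end to end.

The intensity model is multiplicative, the standard model for fully developed
speckle: a piecewise-smooth echogenicity field (background, lesion interior at
``contrast`` times the background level, halo rim, depth-increasing shadow
band) is multiplied by unit-mean gamma-distributed noise that has been blurred
with a small point-spread kernel to mimic the lateral/axial correlation of a
real B-mode speckle pattern.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec",
    "BModeImage",
    "SegmentationMask",
    "SpecDistribution",
    "generate_phantom",
    "generate_dataset",
]

BACKGROUND_LEVEL = 0.55  # mean background echogenicity on the [0, 1] scale


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one phantom; identical specs give identical phantoms.

    Parameters
    ----------
    image_height, image_width : int
        Frame size in pixels, at least 16 each.
    lesion_center : (row, col)
        Lesion center in pixel coordinates (row-major, 0-based).
    lesion_radii : (a, b)
        Semi-axes of the lesion ellipse, in pixels (row semi-axis, col semi-axis).
    margin_irregularity : float
        Amplitude (>= 0) of the band-limited radial perturbation of the lesion
        boundary; 0 gives an exact ellipse, ~0.3 gives the spiculated margins
        typical of malignant masses.
    contrast : float
        Ratio in (0, 1] of lesion mean echogenicity to background mean; < 1 is
        hypoechoic (darker lesion).
    shadow_strength : float
        Attenuation in [0, 1] of the column band beneath the lesion (posterior
        acoustic shadowing); 0 disables it.
    halo_width : float
        Width in pixels (>= 0) of a hyperechoic rim around the lesion.
    speckle_scale : float
        Relative standard deviation (> 0) of the multiplicative speckle before
        point-spread smoothing.
    rng_seed : int
        Seed; same seed, same phantom, bit for bit.
    """

    image_height: int = 64
    image_width: int = 64
    lesion_center: tuple[float, float] = (32.0, 32.0)
    lesion_radii: tuple[float, float] = (12.0, 14.0)
    margin_irregularity: float = 0.0
    contrast: float = 0.4
    shadow_strength: float = 0.0
    halo_width: float = 0.0
    speckle_scale: float = 0.35
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image must be at least 16x16")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError(f"contrast must be in (0, 1], got {self.contrast}")
        if self.margin_irregularity < 0:
            raise ValueError("margin_irregularity must be >= 0")
        if not (0.0 <= self.shadow_strength <= 1.0):
            raise ValueError("shadow_strength must be in [0, 1]")
        if self.halo_width < 0:
            raise ValueError("halo_width must be >= 0")
        if self.speckle_scale <= 0:
            raise ValueError("speckle_scale must be > 0")
        a, b = self.lesion_radii
        if a <= 0 or b <= 0:
            raise ValueError("lesion_radii must be positive")
        r0, c0 = self.lesion_center
        # worst-case boundary excursion: radius inflated by the margin
        # perturbation plus the halo rim must stay inside the frame
        reach_r = a * (1.0 + self.margin_irregularity) + self.halo_width
        reach_c = b * (1.0 + self.margin_irregularity) + self.halo_width
        for name, lo, hi, bound in (
            ("row", r0 - reach_r, r0 + reach_r, self.image_height - 1),
            ("col", c0 - reach_c, c0 + reach_c, self.image_width - 1),
        ):
            if lo < 0 or hi > bound:
                raise ValueError(
                    f"lesion out of frame: {name} extent [{lo:.1f}, {hi:.1f}] "
                    f"exceeds [0, {bound}]"
                )


@dataclass
class BModeImage:
    """A 2-D grayscale intensity raster with provenance metadata."""

    pixels: np.ndarray
    patient_id: str
    source: str = "phantom"  # "phantom" | "file"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if min(self.pixels.shape) < 16:
            raise ValueError("image must be at least 16x16")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be nonnegative")
        if not self.patient_id:
            raise ValueError("patient_id is required (drives grouped splitting)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SegmentationMask:
    """A binary raster aligned to an image; role is truth, seed, or prediction."""

    pixels: np.ndarray
    role: str = "truth"

    _ROLES = ("truth", "seed", "prediction")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be exactly 0 or 1")
        self.pixels = self.pixels.astype(np.uint8)
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Filled (possibly irregular) ellipse on the image grid.

    The boundary is r(theta) = 1 + sum_m a_m cos(m theta + phi_m) in
    normalized elliptical radius, harmonics m = 2..6, with the perturbation
    rescaled so its peak amplitude equals ``margin_irregularity``.
    """
    rr, cc = np.mgrid[0 : spec.image_height, 0 : spec.image_width]
    r0, c0 = spec.lesion_center
    a, b = spec.lesion_radii
    dy = (rr - r0) / a
    dx = (cc - c0) / b
    rho = np.hypot(dy, dx)  # normalized elliptical radius
    if spec.margin_irregularity > 0:
        theta = np.arctan2(dy, dx)
        harmonics = np.arange(2, 7)
        amps = rng.uniform(0.3, 1.0, harmonics.size)
        phases = rng.uniform(0, 2 * np.pi, harmonics.size)
        pert = np.zeros_like(theta)
        for m, am, ph in zip(harmonics, amps, phases):
            pert += am * np.cos(m * theta + ph)
        peak = np.abs(pert).max()
        if peak > 0:
            pert *= spec.margin_irregularity / peak
        boundary = 1.0 + pert
    else:
        boundary = 1.0
    return (rho <= boundary).astype(np.uint8)


def _echogenicity_field(spec: PhantomSpec, mask: np.ndarray) -> np.ndarray:
    """Noise-free piecewise-smooth intensity field on [0, ~1]."""
    field_ = np.full(mask.shape, BACKGROUND_LEVEL, dtype=np.float64)
    field_[mask == 1] = spec.contrast * BACKGROUND_LEVEL

    if spec.halo_width > 0:
        # bright rim: pixels within halo_width outside the lesion
        from scipy.ndimage import distance_transform_edt

        dist_out = distance_transform_edt(mask == 0)
        rim = (mask == 0) & (dist_out <= spec.halo_width)
        field_[rim] = min(1.0, BACKGROUND_LEVEL * 1.45)

    if spec.shadow_strength > 0:
        rows_any = np.any(mask, axis=1)
        if rows_any.any():
            bottom = int(np.max(np.nonzero(rows_any)))
            cols = np.any(mask, axis=0)
            h = mask.shape[0]
            if bottom + 1 < h:
                depth = np.arange(1, h - bottom, dtype=np.float64)
                ramp = np.minimum(1.0, depth / max(1.0, 0.5 * (h - bottom)))
                atten = 1.0 - spec.shadow_strength * ramp  # deepens with depth
                band = np.outer(atten, cols.astype(np.float64))
                band[:, ~cols] = 1.0
                field_[bottom + 1 :, :] *= band
    return field_


def shadow_band(spec: PhantomSpec, mask: np.ndarray) -> np.ndarray:
    """Boolean raster of the posterior-shadow column band (empty if no shadow)."""
    band = np.zeros(mask.shape, dtype=bool)
    if spec.shadow_strength > 0 and mask.any():
        bottom = int(np.max(np.nonzero(np.any(mask, axis=1))))
        cols = np.any(mask, axis=0)
        band[bottom + 1 :, cols] = True
    return band


def _speckle(spec: PhantomSpec, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    # gamma(k, 1/k): mean 1, variance 1/k = speckle_scale^2
    k = 1.0 / spec.speckle_scale**2
    noise = rng.gamma(shape=k, scale=1.0 / k, size=shape)
    # small point-spread blur correlates the grains; 'reflect' keeps mean 1
    return gaussian_filter(noise, sigma=0.7, mode="reflect")


def generate_phantom(spec: PhantomSpec) -> tuple[BModeImage, SegmentationMask]:
    """Generate one speckled B-mode-like image and its ground-truth mask.

    Deterministic in ``spec.rng_seed``.  The mask is 1 exactly inside the
    (possibly irregular) lesion boundary; the lesion interior mean equals
    ``contrast`` times the background mean before speckle; the shadow band, if
    any, is attenuated multiplicatively with depth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    mask = _lesion_mask(spec, rng)
    field_ = _echogenicity_field(spec, mask)
    image = field_ * _speckle(spec, mask.shape, rng)
    np.clip(image, 0.0, None, out=image)
    bmode = BModeImage(
        image,
        patient_id=f"phantom-{spec.rng_seed}",
        source="phantom",
        meta={"spec": spec},
    )
    return bmode, SegmentationMask(mask, role="truth")


def noise_free_field(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """The (field, mask) pair before speckle — the oracle for intensity checks."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    mask = _lesion_mask(spec, rng)
    return _echogenicity_field(spec, mask), mask


@dataclass(frozen=True)
class SpecDistribution:
    """Parameter ranges a dataset of phantoms is drawn from.

    Defaults describe a realistic desk-scale world on a 64x64 grid: clearly
    hypoechoic lesions (contrast 0.30-0.45), radii 9-16 px, mild-to-moderate
    margin irregularity, posterior shadowing in roughly half the cases, light
    halo, fully developed speckle.  Per-patient jitter emulates the same mass
    imaged from multiple orientations.
    """

    image_size: int = 64
    radii_range: tuple[float, float] = (9.0, 16.0)
    contrast_range: tuple[float, float] = (0.30, 0.45)
    irregularity_range: tuple[float, float] = (0.0, 0.15)
    shadow_probability: float = 0.5
    shadow_range: tuple[float, float] = (0.2, 0.5)
    halo_probability: float = 0.3
    halo_range: tuple[float, float] = (1.0, 2.0)
    speckle_range: tuple[float, float] = (0.25, 0.40)
    center_jitter: float = 2.0  # px, between images of one patient
    radius_jitter: float = 0.10  # relative, between images of one patient

    def draw_patient(self, rng: np.random.Generator) -> dict:
        """Base lesion geometry for one patient (one mass)."""
        a = rng.uniform(*self.radii_range)
        b = rng.uniform(*self.radii_range)
        irregularity = rng.uniform(*self.irregularity_range)
        shadow = (
            rng.uniform(*self.shadow_range)
            if rng.random() < self.shadow_probability
            else 0.0
        )
        halo = (
            rng.uniform(*self.halo_range)
            if rng.random() < self.halo_probability
            else 0.0
        )
        reach = max(a, b) * (1 + irregularity) + halo + self.center_jitter + 2
        lo, hi = reach, self.image_size - 1 - reach
        if hi <= lo:
            raise ValueError(
                "spec_distribution ranges leave no room for the lesion center"
            )
        return {
            "center": (rng.uniform(lo, hi), rng.uniform(lo, hi)),
            "radii": (a, b),
            "irregularity": irregularity,
            "contrast": rng.uniform(*self.contrast_range),
            "shadow": shadow,
            "halo": halo,
            "speckle": rng.uniform(*self.speckle_range),
        }

    def view_of(self, base: dict, rng: np.random.Generator, seed: int) -> PhantomSpec:
        """One imaging view of a patient's mass: jittered center and radii."""
        r0, c0 = base["center"]
        a, b = base["radii"]
        jit = lambda: rng.uniform(-self.center_jitter, self.center_jitter)
        scale = 1.0 + rng.uniform(-self.radius_jitter, self.radius_jitter)
        return PhantomSpec(
            image_height=self.image_size,
            image_width=self.image_size,
            lesion_center=(r0 + jit(), c0 + jit()),
            lesion_radii=(a * scale, b * scale),
            margin_irregularity=base["irregularity"],
            contrast=base["contrast"],
            shadow_strength=base["shadow"],
            halo_width=base["halo"],
            speckle_scale=base["speckle"],
            rng_seed=seed,
        )


def generate_dataset(
    n_patients: int,
    images_per_patient: int,
    spec_distribution: SpecDistribution | None = None,
    rng_seed: int = 0,
) -> list[tuple[BModeImage, SegmentationMask]]:
    """Generate a patient-grouped phantom dataset.

    Each patient contributes ``images_per_patient`` views of one lesion
    geometry (jittered center/radii, shared contrast and margin class),
    emulating a clinical dataset in which one mass is imaged from multiple
    orientations.  All images of a patient share a ``patient_id``, which is
    what grouped cross-validation splits on.  Deterministic in ``rng_seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if images_per_patient < 1:
        raise ValueError("images_per_patient must be >= 1")
    dist = spec_distribution or SpecDistribution()
    rng = np.random.default_rng(rng_seed)
    out: list[tuple[BModeImage, SegmentationMask]] = []
    for p in range(n_patients):
        base = dist.draw_patient(rng)
        pid = f"P{p:04d}"
        # margin irregularity is the malignancy analog: irregular, spiculated
        # boundaries are the hallmark of malignant masses on B-mode
        mid = 0.5 * sum(dist.irregularity_range)
        label = "malignant" if base["irregularity"] > mid else "benign"
        for v in range(images_per_patient):
            view_seed = int(rng.integers(0, 2**31 - 1))
            spec = dist.view_of(base, rng, seed=view_seed)
            img, msk = generate_phantom(spec)
            img.patient_id = pid
            img.meta["class"] = label
            out.append((img, msk))
    return out
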