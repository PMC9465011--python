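"""Synthetic VIS-NIR hyperspectral apple scenes for bruise-detection studies.

This module emulates a pushbroom (line-scan) hyperspectral imager viewing
Golden Delicious apples, some of which carry impact bruises.  A scene is a
radiometric cube (lines x samples x bands, digital numbers from a 14-bit
EMCCD model) together with matching dark and white reference frames and a
ground-truth description (apple disk, bruise footprint, severity label).

The spectral model places the absorption features that dominate apple peel
reflectance in 400-1000 nm:

* carotenoids  -- broad valley around 500 nm (450-550 nm),
* chlorophyll  -- narrow valley near 680 nm,
* sugar        -- shallow valley near 820 nm,
* water        -- broad NIR valley centred near 960 nm (750-1000 nm).

Bruising (enzymatic browning plus tissue water redistribution) multiplies
the sound-tissue reflectance by a factor below one that is concentrated in
three regions: a short-wavelength brown-pigment rise centred near 424.5 nm,
the browning band around 554 nm, and a broad NIR depression with structure
near 774.2 and 812.5 nm.  The depression amplitude grows linearly with the
impact energy of the bruising pendulum, so the severity groups
sound < low < medium < high are ordered but overlap at pixel level.

Pixel-to-pixel variability is carried by (a) a multiplicative radial shading
profile over the apple disk (the sphere is brighter at its crown), (b) four
orthonormal latent spectral components with smooth random per-pixel weights,
and (c) additive reflectance texture noise.  The camera adds shot noise,
read noise and 14-bit quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "SEVERITY_ORDER",
    "IMPACT_ENERGY_J",
    "KEY_WAVELENGTHS_NM",
    "SpectralAxis",
    "PendulumConfig",
    "pendulum_energy",
    "CameraModel",
    "AppleSpectralModel",
    "BruiseEffect",
    "SceneGeometry",
    "SceneTruth",
    "HyperCube",
    "Scene",
    "make_apple_scene",
    "generate_cohort",
]

#: severity labels from no impact to the hardest impact
SEVERITY_ORDER = ("sound", "low", "medium", "high")

#: canonical impact energies (J) of the three bruising groups, as produced by
#: the pendulum protocol (release angles 27/38/50 degrees)
IMPACT_ENERGY_J = {"sound": 0.0, "low": 0.33, "medium": 0.66, "high": 1.11}

#: wavebands (nm) around which the bruise signature is planted; these are the
#: bands a selection procedure is expected to recover
KEY_WAVELENGTHS_NM = (424.5, 553.9, 774.2, 812.5)


# --------------------------------------------------------------------------
# spectral axis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralAxis:
    """Band centers of a hyperspectral cube.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing band-center wavelengths in nanometres.
    """

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("spectral axis needs at least two bands")
        if not np.all(np.diff(lam) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", lam)

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size

    @property
    def sampling_interval_nm(self) -> float:
        """Median band spacing (exact spacing for a uniform grid)."""
        return float(np.median(np.diff(self.wavelengths_nm)))

    @classmethod
    def default(cls, start_nm: float = 400.0, stop_nm: float = 1000.0,
                step_nm: float = 5.0, anchor_nm: float = 553.9) -> "SpectralAxis":
        """Uniform grid anchored so 553.9 nm is an exact band center.

        The grid is extended outward until it covers ``[start_nm, stop_nm]``;
        with the defaults every wavelength in :data:`KEY_WAVELENGTHS_NM` has
        a band center within half a grid step.
        """
        k_lo = math.floor((start_nm - anchor_nm) / step_nm)
        k_hi = math.ceil((stop_nm - anchor_nm) / step_nm)
        lam = anchor_nm + step_nm * np.arange(k_lo, k_hi + 1)
        return cls(lam)

    def index_of(self, nm: float, tol_nm: float | None = None) -> int:
        """Index of the band center nearest ``nm``.

        Raises ``ValueError`` if the nearest center is farther than
        ``tol_nm`` (default: half the sampling interval).
        """
        idx = int(np.argmin(np.abs(self.wavelengths_nm - nm)))
        if tol_nm is None:
            tol_nm = 0.5 * self.sampling_interval_nm + 1e-9
        if abs(self.wavelengths_nm[idx] - nm) > tol_nm:
            raise ValueError(
                f"no band center within {tol_nm:g} nm of {nm:g} nm"
            )
        return idx

    def __eq__(self, other: object) -> bool:  # value equality for cube checks
        return (
            isinstance(other, SpectralAxis)
            and self.wavelengths_nm.shape == other.wavelengths_nm.shape
            and np.allclose(self.wavelengths_nm, other.wavelengths_nm)
        )


# --------------------------------------------------------------------------
# bruising pendulum
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PendulumConfig:
    """Geometry of the ball-on-rod bruising pendulum."""

    ball_mass_kg: float = 0.067
    rod_mass_kg: float = 0.663
    rod_length_m: float = 0.68
    release_angle_deg: float = 50.0
    g: float = 9.81

    def __post_init__(self) -> None:
        for name in ("ball_mass_kg", "rod_mass_kg", "rod_length_m", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.release_angle_deg <= 90.0):
            raise ValueError("release_angle_deg must be in [0, 90]")


def pendulum_energy(cfg: PendulumConfig) -> float:
    """Impact energy (J) released by the pendulum.

    The ball at the rod tip rises by ``h = L (1 - cos theta)`` and the rod's
    center of mass by ``h / 2``; the energy is

        E = m_b g h + m_r g h / 2.

    Note: with the nominal 67 g ball / 663 g, 68 cm rod this evaluates to
    0.950, 0.564 and 0.290 J at 50, 38 and 27 degrees, i.e. about 15% below
    the nominal group energies in :data:`IMPACT_ENERGY_J`; the nominal values
    are retained as the severity parameterization (see docs/methods.md).
    """
    h = cfg.rod_length_m * (1.0 - math.cos(math.radians(cfg.release_angle_deg)))
    return cfg.g * h * (cfg.ball_mass_kg + 0.5 * cfg.rod_mass_kg)


# --------------------------------------------------------------------------
# camera
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Parametric EMCCD + spectrograph + halogen-illumination response.

    ``throughput`` gives the expected signal rate (DN per second per
    detector row) for a perfect (reflectance 1) diffuse target.  It is a
    two-sided Gaussian in wavelength, peaking near 553.9 nm and falling off
    faster toward the blue than toward the NIR, which reproduces the
    qualitative behaviour of a silicon EMCCD behind halogen lamps: the green
    reference band saturates first and the 424.5 nm band needs the widest
    spectral ROI.
    """

    peak_rate_dn_per_s: float = 88_000.0
    peak_nm: float = 560.0
    sigma_blue_nm: float = 130.0
    sigma_red_nm: float = 300.0
    adc_bits: int = 14
    dark_offset_dn: float = 100.0
    read_noise_dn: float = 2.0
    electrons_per_dn: float = 4.0
    shot_noise: bool = True

    @property
    def full_scale_dn(self) -> int:
        return 2 ** self.adc_bits - 1

    def throughput(self, wavelengths_nm: np.ndarray | float) -> np.ndarray:
        """Signal rate (DN/s/row) at the given wavelengths; strictly positive."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        sigma = np.where(lam < self.peak_nm, self.sigma_blue_nm, self.sigma_red_nm)
        return self.peak_rate_dn_per_s * np.exp(-(((lam - self.peak_nm) / sigma) ** 2))

    def expected_dn(self, reflectance: np.ndarray, exposure_s: float,
                    wavelengths_nm: np.ndarray) -> np.ndarray:
        """Noise-free expected DN (offset + signal), before clipping."""
        rate = self.throughput(wavelengths_nm)
        return self.dark_offset_dn + rate * exposure_s * np.asarray(reflectance)

    def digitize(self, expected_dn: np.ndarray,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        """Apply shot noise, read noise and 14-bit clipping/rounding.

        Shot noise acts on the photo-signal above the dark offset at
        ``electrons_per_dn`` conversion gain; read noise is Gaussian in DN.
        With ``rng=None`` the expected value is returned (noiseless limit),
        still clipped and rounded.
        """
        signal = np.clip(np.asarray(expected_dn, dtype=float) - self.dark_offset_dn,
                         0.0, None)
        if rng is not None and self.shot_noise:
            electrons = rng.poisson(signal * self.electrons_per_dn)
            signal = electrons / self.electrons_per_dn
        dn = self.dark_offset_dn + signal
        if rng is not None and self.read_noise_dn > 0:
            dn = dn + rng.normal(0.0, self.read_noise_dn, size=dn.shape)
        return np.clip(np.rint(dn), 0, self.full_scale_dn)


# --------------------------------------------------------------------------
# apple spectral model
# --------------------------------------------------------------------------

def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((lam - center) / width) ** 2))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _orthonormal_components(lam: np.ndarray) -> np.ndarray:
    """Four smooth orthonormal spectral components (bands x 4).

    Seeded by interpretable shapes -- a chlorophyll-like dip, a red/NIR
    tilt, a broad green hump and a curvature term -- then Gram-Schmidt
    orthonormalized in that order.
    """
    seeds = np.stack(
        [
            -_gauss(lam, 680.0, 50.0),
            (lam - 700.0) / 300.0,
            _gauss(lam, 500.0, 60.0),
            np.cos((lam - 400.0) / 600.0 * 2.0 * np.pi),
        ],
        axis=1,
    )
    q = np.zeros_like(seeds)
    for k in range(seeds.shape[1]):
        v = seeds[:, k] - q[:, :k] @ (q[:, :k].T @ seeds[:, k])
        q[:, k] = v / np.linalg.norm(v)
    return q


@dataclass(frozen=True)
class AppleSpectralModel:
    """Generative model of sound Golden Delicious peel reflectance."""

    axis: SpectralAxis
    feature_depths: Mapping[str, float] = field(
        default_factory=lambda: {
            "carotenoid": 0.12,
            "chlorophyll": 0.10,
            "sugar": 0.05,
            "water": 0.15,
        }
    )
    latent_weight_sd: tuple[float, float, float, float] = (0.18, 0.060, 0.015, 0.008)
    #: apple-to-apple spread of the latent weights (pigment differences
    #: between fruit), on top of the within-apple per-pixel fields
    apple_weight_sd: tuple[float, float, float, float] = (0.09, 0.08, 0.015, 0.008)
    noise_sd: float = 0.004

    # absorption-feature centers/widths (nm); fixed phenomenology
    _FEATURES = {
        "carotenoid": (500.0, 35.0),
        "chlorophyll": (680.0, 12.0),
        "sugar": (820.0, 18.0),
        "water": (960.0, 55.0),
    }

    def baseline_reflectance(self) -> np.ndarray:
        """Smooth sound-peel reflectance on the axis, in (0, 1)."""
        lam = self.axis.wavelengths_nm
        base = 0.30 + 0.42 * _sigmoid((lam - 530.0) / 60.0)
        for name, (center, width) in self._FEATURES.items():
            base = base - self.feature_depths.get(name, 0.0) * _gauss(lam, center, width)
        return base

    def latent_components(self) -> np.ndarray:
        """Orthonormal (bands x 4) latent spectral variability basis."""
        return _orthonormal_components(self.axis.wavelengths_nm)


# --------------------------------------------------------------------------
# bruise effect
# --------------------------------------------------------------------------

def bruise_signature(lam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spectral shapes of the browning and NIR depressions (unit peak-ish).

    Returns ``(browning, nir)``: browning combines the 554 nm band with the
    short-wavelength brown-pigment rise near 424.5 nm; the NIR term is a
    broad positive depression over 750-1000 nm with local structure near
    774.2 and 812.5 nm.
    """
    browning = _gauss(lam, 554.0, 30.0) + 1.3 * _gauss(lam, 424.5, 34.0)
    nir = (
        0.40 * _sigmoid((lam - 745.0) / 15.0)
        + 0.45 * _gauss(lam, 774.2, 13.0)
        + 0.50 * _gauss(lam, 812.5, 18.0)
    )
    return browning, nir


@dataclass(frozen=True)
class BruiseEffect:
    """Severity-scaled multiplicative reflectance depression of a bruise.

    ``browning_depression`` and ``nir_depression`` are the peak fractional
    reflectance reductions of the two spectral signature terms; both grow
    linearly with impact energy.  ``footprint_axes_px`` are the ellipse
    semi-axes of the bruised area.
    """

    severity_level: str
    impact_energy_J: float
    browning_depression: float
    nir_depression: float
    footprint_axes_px: tuple[float, float] = (9.0, 7.0)

    #: linear impact-energy -> depression calibration (offset, slope per J)
    BROWNING_MAP = (0.12, 0.22)
    NIR_MAP = (0.10, 0.08)

    def __post_init__(self) -> None:
        if self.severity_level not in SEVERITY_ORDER:
            raise ValueError(f"unknown severity {self.severity_level!r}")
        if not (0.0 <= self.browning_depression < 1.0
                and 0.0 <= self.nir_depression < 1.0):
            raise ValueError("depression fractions must lie in [0, 1)")

    @classmethod
    def from_severity(cls, severity: str, energy_J: float | None = None,
                      **kwargs) -> "BruiseEffect":
        """Standard severity -> effect mapping (linear in impact energy)."""
        if severity not in SEVERITY_ORDER:
            raise ValueError(f"unknown severity {severity!r}")
        if energy_J is None:
            energy_J = IMPACT_ENERGY_J[severity]
        if severity == "sound" or energy_J == 0.0:
            return cls(severity, 0.0, 0.0, 0.0, **kwargs)
        b0, b1 = cls.BROWNING_MAP
        n0, n1 = cls.NIR_MAP
        return cls(severity, energy_J, b0 + b1 * energy_J, n0 + n1 * energy_J,
                   **kwargs)

    @property
    def is_bruised(self) -> bool:
        return self.severity_level != "sound" and self.browning_depression > 0

    def multiplier(self, lam: np.ndarray, amplitude: float = 1.0) -> np.ndarray:
        """Reflectance multiplier at full bruise-core ``amplitude=1``."""
        browning, nir = bruise_signature(lam)
        m = 1.0 - amplitude * (self.browning_depression * browning
                               + self.nir_depression * nir)
        return m


# --------------------------------------------------------------------------
# scene assembly
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneGeometry:
    """Image raster and apple-disk layout of one scene."""

    lines: int = 80
    samples: int = 80
    apple_radius_px: float = 30.0
    background_reflectance: float = 0.03
    shading_falloff: float = 0.55  # brightness drop at the disk edge
    exposure_s: float = 0.17      # full-resolution acquisition exposure
    n_reference_lines: int = 10   # averaged white/dark reference lines

    def __post_init__(self) -> None:
        margin = min(self.lines, self.samples) / 2.0
        if self.apple_radius_px >= margin:
            raise ValueError("apple disk does not fit inside the image")


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth of a synthetic scene (evaluation only)."""

    apple_mask: np.ndarray   # bool (lines, samples)
    bruise_mask: np.ndarray  # bool (lines, samples), subset of apple_mask
    severity_level: str

    def __post_init__(self) -> None:
        if self.bruise_mask.shape != self.apple_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.bruise_mask & ~self.apple_mask):
            raise ValueError("bruise mask must lie inside the apple mask")


@dataclass(frozen=True)
class HyperCube:
    """A (lines, samples, bands) raster with its spectral axis.

    ``kind`` is one of ``raw``, ``dark``, ``white`` (digital numbers) or
    ``reflectance``.  Reference frames use ``lines == 1`` and broadcast
    along the scan direction (line-scan convention).
    """

    data: np.ndarray
    axis: SpectralAxis
    kind: str = "raw"

    _KINDS = ("raw", "dark", "white", "reflectance")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, samples, bands)")
        if d.shape[2] != self.axis.n_bands:
            raise ValueError("band count does not match the spectral axis")
        object.__setattr__(self, "data", d)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band(self, nm: float) -> np.ndarray:
        """The 2-D image of the band nearest ``nm``."""
        return self.data[:, :, self.axis.index_of(nm, tol_nm=np.inf)]


@dataclass(frozen=True)
class Scene:
    """One simulated apple acquisition: cubes, references and truth."""

    raw: HyperCube
    dark: HyperCube
    white: HyperCube
    truth: SceneTruth
    reflectance_truth: HyperCube  # noiseless scene reflectance
    effect: BruiseEffect
    geometry: SceneGeometry
    seed: int


def _reference_frames(camera: CameraModel, axis: SpectralAxis,
                      geometry: SceneGeometry,
                      rng: np.random.Generator) -> tuple[HyperCube, HyperCube]:
    lam = axis.wavelengths_nm
    shape = (geometry.n_reference_lines, geometry.samples, axis.n_bands)
    white_exp = np.broadcast_to(
        camera.expected_dn(0.99, geometry.exposure_s, lam), shape
    )
    dark_exp = np.full(shape, camera.dark_offset_dn)
    white = camera.digitize(white_exp, rng).mean(axis=0, keepdims=True)
    dark = camera.digitize(dark_exp, rng).mean(axis=0, keepdims=True)
    return (HyperCube(white, axis, "white"), HyperCube(dark, axis, "dark"))


def make_apple_scene(model: AppleSpectralModel,
                     effect: BruiseEffect,
                     geometry: SceneGeometry | None = None,
                     seed: int = 0,
                     camera: CameraModel | None = None,
                     severity_jitter_sd: float = 0.08) -> Scene:
    """Simulate one apple under the line-scan imager.

    Builds the noiseless scene reflectance (baseline + latent variability,
    radial shading, multiplicative bruise depression over an elliptical
    footprint), pushes it through the camera model to a raw DN cube, and
    acquires averaged white/dark reference frames.  Identical ``seed``
    (with identical parameters) reproduces the scene bit for bit.
    """
    geometry = geometry or SceneGeometry()
    camera = camera or CameraModel()
    axis = model.axis
    lam = axis.wavelengths_nm
    rng = np.random.default_rng(seed)

    ny, nx = geometry.lines, geometry.samples
    cy = ny / 2.0 + rng.uniform(-1.5, 1.5)
    cx = nx / 2.0 + rng.uniform(-1.5, 1.5)
    radius = geometry.apple_radius_px * rng.uniform(0.95, 1.05)
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / radius**2
    apple = r2 <= 1.0
    if not apple.any():
        raise ValueError("geometry produced an empty apple disk")

    # spherical shading: multiplicative radial falloff (drives PC1)
    shading = 1.0 - geometry.shading_falloff * np.clip(r2, 0.0, 1.0)

    # latent spectral variability: a per-apple pigment offset plus smooth
    # per-pixel weight fields
    comps = model.latent_components()
    weights = np.empty((ny, nx, 4))
    for k, sd in enumerate(model.latent_weight_sd):
        apple_sd = model.apple_weight_sd[k]
        offset = np.clip(rng.normal(0.0, apple_sd), -3.0 * apple_sd, 3.0 * apple_sd)
        w = gaussian_filter(rng.standard_normal((ny, nx)), sigma=3.0)
        w = w / max(w.std(), 1e-12) * sd
        weights[:, :, k] = offset + np.clip(w, -4.0 * sd, 4.0 * sd)
    spectra = model.baseline_reflectance()[None, None, :] + weights @ comps.T

    # bruise footprint: soft-edged ellipse placed off-center on the disk
    bruise_mask = np.zeros((ny, nx), dtype=bool)
    amplitude = np.zeros((ny, nx))
    if effect.is_bruised:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        bcy = cy + 0.45 * radius * np.sin(theta)
        bcx = cx + 0.45 * radius * np.cos(theta)
        a, b = effect.footprint_axes_px
        a *= rng.uniform(0.85, 1.15)
        b *= rng.uniform(0.85, 1.15)
        phi = rng.uniform(0.0, np.pi)
        u = (yy - bcy) * np.cos(phi) + (xx - bcx) * np.sin(phi)
        v = -(yy - bcy) * np.sin(phi) + (xx - bcx) * np.cos(phi)
        rho2 = (u / a) ** 2 + (v / b) ** 2
        amplitude = np.sqrt(np.clip(1.0 - rho2, 0.0, None))
        amplitude *= apple * rng.normal(1.0, severity_jitter_sd)
        amplitude = np.clip(amplitude, 0.0, 1.0)
        bruise_mask = (amplitude >= 0.15) & apple

    browning, nir = bruise_signature(lam)
    depression = (effect.browning_depression * browning
                  + effect.nir_depression * nir)
    mult = 1.0 - amplitude[:, :, None] * depression[None, None, :]

    reflectance = spectra * shading[:, :, None] * mult
    if model.noise_sd > 0:
        reflectance = reflectance + rng.normal(
            0.0, model.noise_sd, size=reflectance.shape
        )
    reflectance = np.where(apple[:, :, None], reflectance,
                           geometry.background_reflectance)
    in_apple = reflectance[apple]
    if in_apple.min() <= 0.0 or in_apple.max() >= 1.0:
        raise ValueError(
            "scene reflectance left (0, 1); the spectral model or bruise "
            "effect is misconfigured"
        )

    expected = camera.expected_dn(reflectance, geometry.exposure_s, lam)
    raw = camera.digitize(expected, rng)
    white, dark = _reference_frames(camera, axis, geometry, rng)

    truth = SceneTruth(apple, bruise_mask, effect.severity_level)
    return Scene(
        raw=HyperCube(raw, axis, "raw"),
        dark=dark,
        white=white,
        truth=truth,
        reflectance_truth=HyperCube(reflectance.astype(np.float64), axis,
                                    "reflectance"),
        effect=effect,
        geometry=geometry,
        seed=seed,
    )


def generate_cohort(n_per_group: int,
                    groups: Sequence[str] = SEVERITY_ORDER,
                    seed: int = 0,
                    model: AppleSpectralModel | None = None,
                    geometry: SceneGeometry | None = None,
                    camera: CameraModel | None = None) -> list[Scene]:
    """Simulate ``n_per_group`` apples for each severity group.

    Scenes are mutually independent given ``seed``; the same seed
    reproduces the cohort element-wise.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    groups = list(groups)
    if not groups:
        raise ValueError("groups must be non-empty")
    for g in groups:
        if g not in SEVERITY_ORDER:
            raise ValueError(f"unknown severity group {g!r}")
    if model is None:
        model = AppleSpectralModel(SpectralAxis.default())
    child_seeds = np.random.SeedSequence(seed).generate_state(
        n_per_group * len(groups)
    ) % (2**31)
    scenes: list[Scene] = []
    i = 0
    for g in groups:
        for _ in range(n_per_group):
            effect = BruiseEffect.from_severity(g)
            scenes.append(
                make_apple_scene(model, effect, geometry, int(child_seeds[i]),
                                 camera)
            )
            i += 1
    return scenes
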