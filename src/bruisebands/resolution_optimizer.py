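"""Exposure-time / spectral-ROI / dynamic-range optimization.

A Random-Track readout bins a contiguous block of detector rows (a spectral
ROI) into one output waveband.  For a fixed exposure the white-reference
signal of a band is the summed throughput of its rows times the exposure;
the fraction of the 14-bit full scale this reaches is the band's dynamic
range.  The reference band (553.9 nm, where system throughput peaks) sets
the exposure by demanding 90% of full scale; the remaining key wavebands
are then widened until they reach a target fraction (25, 50 or 90%) of
full scale.  Each feasible (exposure, fraction) combination is emulated by
re-acquiring the synthetic scenes through the camera model at that exposure
and binning, and ranked by the resulting classification-map quality:
apple-level accuracy first, then fewest scattered false-positive pixels,
then shortest exposure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import classification_maps as cmaps
from .band_selection import make_classifier
from .calibration import ReflectanceCube
from .pixel_extraction import PixelSpectraDataset
from .synthetic_data import CameraModel, HyperCube, Scene, SpectralAxis

__all__ = [
    "BandROI",
    "BinningCombination",
    "CombinationScore",
    "predict_signal",
    "solve_roi_width",
    "solve_exposure",
    "enumerate_combinations",
    "bin_cube",
    "bin_spectra",
    "acquire_combination",
    "score_combinations",
]

WHITE_REFLECTANCE = 0.99   # Spectralon reference panel
SATURATION_TOLERANCE = 1.15  # uncapped white fraction beyond which a ROI is rejected


@dataclass(frozen=True)
class BandROI:
    """One output waveband: center, symmetric row block, dynamic-range bookkeeping."""

    center_nm: float
    rows: int                  # odd number of detector rows binned
    roi_width_nm: float
    target_fraction: float
    achieved_fraction: float   # predicted white signal / full scale, capped at 1
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.rows < 1 or self.rows % 2 == 0:
            raise ValueError("rows must be a positive odd count")
        if not (0.0 < self.achieved_fraction <= 1.0):
            raise ValueError("achieved_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class BinningCombination:
    """One row of the exposure/bandwidth enumeration (reference band first)."""

    id: int
    exposure_s: float
    rois: tuple[BandROI, ...]

    @property
    def centers_nm(self) -> tuple[float, ...]:
        return tuple(r.center_nm for r in self.rois)


@dataclass(frozen=True)
class CombinationScore:
    combination: BinningCombination
    pixel_accuracy: float
    false_positive_pixels: int
    apple_accuracy: float
    flagged: bool = False   # degenerate binned features, not scored


def _roi_indices(axis: SpectralAxis, center_nm: float, rows: int) -> np.ndarray:
    """Detector-row (band) indices of a symmetric ROI; errors at the axis edge.

    Odd row counts are centered; an even count takes the extra row on the
    long-wavelength side.
    """
    c = axis.index_of(center_nm, tol_nm=np.inf)
    lo, hi = c - (rows - 1) // 2, c + rows // 2
    if lo < 0 or hi >= axis.n_bands:
        raise ValueError(
            f"{rows}-row ROI at {center_nm:g} nm leaves the spectral axis"
        )
    return np.arange(lo, hi + 1)


def predict_signal(camera: CameraModel, axis: SpectralAxis, center_nm: float,
                   rows: int, exposure_s: float,
                   reference_reflectance: float = 1.0) -> tuple[float, bool]:
    """Predicted white-target DN of a binned band, capped at full scale.

    DN = exposure * sum over ROI rows of throughput(row) * reflectance;
    the boolean flags saturation (cap reached).  Strictly increasing in
    exposure and row count until the cap.
    """
    idx = _roi_indices(axis, center_nm, rows)
    rate = camera.throughput(axis.wavelengths_nm[idx]).sum()
    if rate <= 0:
        raise ValueError("ROI has zero throughput")
    dn = exposure_s * rate * reference_reflectance
    full = camera.full_scale_dn
    return (min(dn, full), dn > full)


def solve_roi_width(camera: CameraModel, axis: SpectralAxis, center_nm: float,
                    exposure_s: float, target_fraction: float) -> BandROI:
    """Smallest symmetric ROI whose white-reference signal reaches the target.

    Row counts grow 1, 3, 5, ... about the center; the achieved fraction is
    recorded (capped at 1 with a saturation flag when the white would
    clip).  Raises with the maximum achievable fraction when the target is
    unreachable inside the axis.
    """
    full = camera.full_scale_dn
    rows = 1
    best = 0.0
    while True:
        try:
            dn, sat = predict_signal(camera, axis, center_nm, rows, exposure_s,
                                     WHITE_REFLECTANCE)
        except ValueError:
            raise ValueError(
                f"target fraction {target_fraction:g} at {center_nm:g} nm "
                f"unreachable within the axis (max achievable {best:.3f})"
            ) from None
        frac = dn / full
        if frac >= target_fraction - 1e-9:
            return BandROI(center_nm, rows, rows * axis.sampling_interval_nm,
                           target_fraction, frac, sat)
        best = max(best, frac)
        rows += 2


def solve_exposure(camera: CameraModel, axis: SpectralAxis,
                   reference_center_nm: float = 553.9, rows: int = 1,
                   target_fraction: float = 0.90) -> float:
    """Exposure for which the reference ROI reaches its dynamic-range target.

    Inverse-proportional to the summed throughput of the ROI rows, so wider
    reference bandwidths yield proportionally shorter exposures.
    """
    idx = _roi_indices(axis, reference_center_nm, rows)
    rate = camera.throughput(axis.wavelengths_nm[idx]).sum()
    if rate <= 0:
        raise ValueError("reference ROI has zero throughput")
    return target_fraction * camera.full_scale_dn / (rate * WHITE_REFLECTANCE)


def enumerate_combinations(camera: CameraModel, axis: SpectralAxis,
                           key_wavelengths_nm: tuple[float, ...],
                           reference_center_nm: float = 553.9,
                           reference_rows_levels: tuple[int, ...] = (1, 3, 5, 9),
                           fraction_grid: tuple[float, ...] = (0.25, 0.50, 0.90),
                           reference_fraction: float = 0.90,
                           ) -> tuple[list[BinningCombination], list[str]]:
    """All feasible (exposure level x side-band fraction) combinations.

    Per exposure level the reference band is fixed at 90% of full scale and
    both remaining key wavebands are widened to a common target fraction.
    A combination is skipped when a side band's single-row signal already
    exceeds its target, when the target is unreachable inside the axis, or
    when the solved ROI would saturate the white reference by more than
    ``SATURATION_TOLERANCE``.  Skips are reported as log strings.
    """
    if len(key_wavelengths_nm) < 2:
        raise ValueError("need at least two key wavelengths")
    side_bands = [w for w in key_wavelengths_nm
                  if abs(w - reference_center_nm) > 1e-6]
    if len(side_bands) == len(key_wavelengths_nm):
        raise ValueError("reference band must be one of the key wavelengths")
    full = camera.full_scale_dn
    combos: list[BinningCombination] = []
    log: list[str] = []
    cid = 1
    for ref_rows in reference_rows_levels:
        exposure = solve_exposure(camera, axis, reference_center_nm, ref_rows,
                                  reference_fraction)
        ref_roi = solve_roi_width(camera, axis, reference_center_nm, exposure,
                                  reference_fraction)
        for frac in fraction_grid:
            rois = [ref_roi]
            ok = True
            for w in side_bands:
                min_dn, _ = predict_signal(camera, axis, w, 1, exposure,
                                           WHITE_REFLECTANCE)
                if min_dn / full > frac:
                    log.append(
                        f"exposure {exposure:.4g}s, {w:g} nm: minimum width "
                        f"already exceeds {frac:.0%}"
                    )
                    ok = False
                    break
                try:
                    roi = solve_roi_width(camera, axis, w, exposure, frac)
                except ValueError as exc:
                    log.append(f"exposure {exposure:.4g}s, {w:g} nm: {exc}")
                    ok = False
                    break
                uncapped = (exposure
                            * camera.throughput(
                                axis.wavelengths_nm[_roi_indices(axis, w, roi.rows)]
                            ).sum() * WHITE_REFLECTANCE) / full
                if uncapped > SATURATION_TOLERANCE:
                    log.append(
                        f"exposure {exposure:.4g}s, {w:g} nm: {frac:.0%} ROI "
                        f"would saturate the white reference ({uncapped:.2f}x)"
                    )
                    ok = False
                    break
                rois.append(roi)
            if ok:
                combos.append(BinningCombination(cid, exposure, tuple(rois)))
                cid += 1
    return combos, log


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------

def bin_cube(cube: HyperCube | ReflectanceCube, combo: BinningCombination,
             camera: CameraModel | None = None) -> tuple[np.ndarray, tuple[float, ...]]:
    """Bin a cube to the combination's wavebands.

    Raw-domain cubes (DN) sum their ROI rows and clip at full scale, like
    the on-chip binning of a Random-Track readout; reflectance cubes take a
    throughput-weighted mean so a single-row ROI reproduces the original
    band exactly.  Returns (lines, samples, n_rois) plus the band centers.
    """
    camera = camera or CameraModel()
    axis = cube.axis
    is_raw = isinstance(cube, HyperCube) and cube.kind in ("raw", "dark", "white")
    out = np.empty(cube.data.shape[:2] + (len(combo.rois),), dtype=float)
    for j, roi in enumerate(combo.rois):
        idx = _roi_indices(axis, roi.center_nm, roi.rows)
        block = cube.data[:, :, idx]
        if is_raw:
            out[:, :, j] = np.clip(block.sum(axis=2), 0, camera.full_scale_dn)
        else:
            w = camera.throughput(axis.wavelengths_nm[idx])
            out[:, :, j] = (block * w).sum(axis=2) / w.sum()
    return out, combo.centers_nm


def bin_spectra(spectra: np.ndarray, axis: SpectralAxis,
                combo: BinningCombination, camera: CameraModel | None = None,
                white_reflectance: float = WHITE_REFLECTANCE) -> np.ndarray:
    """Bin (n, bands) reflectance spectra as a flat-fielded acquisition would.

    Throughput-weighted mean over each ROI divided by the white-panel
    reflectance, matching the flat-field estimate produced by
    :func:`acquire_combination`.
    """
    camera = camera or CameraModel()
    out = np.empty((spectra.shape[0], len(combo.rois)))
    for j, roi in enumerate(combo.rois):
        idx = _roi_indices(axis, roi.center_nm, roi.rows)
        w = camera.throughput(axis.wavelengths_nm[idx])
        out[:, j] = (spectra[:, idx] * w).sum(axis=1) / w.sum() / white_reflectance
    return out


def acquire_combination(scene: Scene, combo: BinningCombination,
                        camera: CameraModel | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[np.ndarray, tuple[float, ...]]:
    """Random-Track acquisition of a scene at a combination's parameters.

    Re-images the scene's noiseless reflectance truth at the combination's
    exposure: each output band is the shot-noise-limited, read-noise-added,
    14-bit-clipped sum of its ROI rows, flat-fielded against white/dark
    references acquired the same way.  Returns the multispectral
    reflectance image and its band centers.
    """
    camera = camera or CameraModel()
    if rng is None:
        rng = np.random.default_rng(scene.seed + 7_777)
    axis = scene.reflectance_truth.axis
    lam = axis.wavelengths_nm
    refl = scene.reflectance_truth.data
    ny, nx = refl.shape[:2]
    n_ref = scene.geometry.n_reference_lines
    out = np.empty((ny, nx, len(combo.rois)))
    for j, roi in enumerate(combo.rois):
        idx = _roi_indices(axis, roi.center_nm, roi.rows)
        rate = camera.throughput(lam[idx])
        signal = combo.exposure_s * (refl[:, :, idx] * rate).sum(axis=2)
        raw = camera.digitize(camera.dark_offset_dn + signal, rng)
        white_sig = combo.exposure_s * rate.sum() * WHITE_REFLECTANCE
        white = camera.digitize(
            np.full((n_ref, nx), camera.dark_offset_dn + white_sig), rng
        ).mean(axis=0)
        dark = camera.digitize(
            np.full((n_ref, nx), camera.dark_offset_dn), rng
        ).mean(axis=0)
        denom = np.where(white > dark, white - dark, np.nan)
        out[:, :, j] = (raw - dark[None, :]) / denom[None, :]
    return out, combo.centers_nm


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def evaluate_combination(combo: BinningCombination, scenes: list[Scene],
                         classifier_id: str, ds: PixelSpectraDataset,
                         camera: CameraModel | None = None, seed: int = 0,
                         opening_radius: int = 1, closing_radius: int = 1,
                         min_area: int = 10) -> cmaps.DetectionReport | None:
    """Retrain on binned training spectra and map/score a cohort.

    Returns ``None`` when the binned training features are degenerate
    (zero variance in some band), in which case the combination cannot be
    modelled.
    """
    camera = camera or CameraModel()
    X_tr, y_tr = ds.partition("train")
    Xb = bin_spectra(X_tr, ds.axis, combo, camera)
    if np.any(Xb.std(axis=0) == 0):
        return None
    clf = make_classifier(classifier_id, Xb)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xb, y_tr)
    rng = np.random.default_rng(seed)
    decisions, truths = [], []
    confusion = np.zeros((2, 2), dtype=int)
    fp_total = 0
    for scene in scenes:
        ms, centers = acquire_combination(
            scene, combo, camera, np.random.default_rng(rng.integers(2**31))
        )
        apple = cmaps.mask_background(ms[:, :, 0])
        cmap = cmaps.classify_pixels(ms, clf, apple, centers)
        cmap = cmaps.clean_map(cmap, opening_radius, closing_radius)
        decisions.append(cmaps.apple_decision(cmap.cleaned, min_area))
        truths.append(scene.truth.bruise_mask.any())
        s = cmaps.score_map(cmap, scene.truth.bruise_mask)
        confusion += s["confusion"]
        fp_total += s["false_positives"]
    return cmaps.DetectionReport(decisions, truths, confusion, fp_total)


def score_combinations(combos: list[BinningCombination], scenes: list[Scene],
                       classifier_id: str, ds: PixelSpectraDataset,
                       camera: CameraModel | None = None, seed: int = 0,
                       opening_radius: int = 1, closing_radius: int = 1,
                       min_area: int = 10,
                       ) -> tuple[list[CombinationScore], BinningCombination]:
    """Retrain, map and rank every binning combination on a cohort.

    For each combination the classifier is retrained on the binned training
    spectra, every scene is re-acquired at the combination's parameters and
    classified, the map is cleaned, and the combination is scored by pooled
    pixel accuracy, scattered false-positive pixels after morphology and
    apple-level accuracy.  The best combination maximizes
    (apple accuracy, -false positives, -exposure) lexicographically.
    """
    scores: list[CombinationScore] = []
    for combo in combos:
        report = evaluate_combination(combo, scenes, classifier_id, ds, camera,
                                      seed, opening_radius, closing_radius,
                                      min_area)
        if report is None:
            scores.append(CombinationScore(combo, float("nan"), 0, float("nan"),
                                           flagged=True))
            continue
        scores.append(CombinationScore(combo, report.pixel_accuracy,
                                       report.false_positive_pixels,
                                       report.apple_accuracy))
    usable = [s for s in scores if not s.flagged]
    if not usable:
        raise ValueError("no combination could be scored")
    best = max(usable, key=lambda s: (s.apple_accuracy, -s.false_positive_pixels,
                                      -s.combination.exposure_s))
    return scores, best.combination
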