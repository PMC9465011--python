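"""Labeled bruise/sound pixel-spectra extraction via PC score images.

A per-scene PCA over apple pixels orders the variance structure of the
reflectance cube: the first component tracks the spherical shading of the
fruit, the second the pigment-driven surface variability, and the bruise
contrast concentrates in the third (sometimes fourth) score image.  Bruise
pixels are selected by thresholding that score image (Otsu, restricted to
apple pixels, keeping only pixels well away from the threshold), which
automates the visual pick of clearly bruised vs clearly sound regions; the
spectra themselves are always read from the original reflectance cube at
the selected coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split

from .calibration import ReflectanceCube
from .synthetic_data import Scene, SceneTruth, SpectralAxis

__all__ = [
    "PCDecomposition",
    "PixelSpectraDataset",
    "pca_cube",
    "select_label_pixels",
    "split_dataset",
    "extract_cohort_dataset",
]


@dataclass(frozen=True)
class PCDecomposition:
    """PCA of apple-pixel spectra: loadings, variance shares, score images."""

    loadings: np.ndarray                 # (bands, K), unit-norm columns
    explained_variance_ratio: np.ndarray  # (K,)
    score_images: np.ndarray             # (K, lines, samples), NaN off-apple
    mean_spectrum: np.ndarray            # (bands,)
    axis: SpectralAxis
    apple_mask: np.ndarray               # bool (lines, samples)


def pca_cube(cube: ReflectanceCube, apple_mask: np.ndarray,
             n_components: int = 4) -> PCDecomposition:
    """Mean-centered PCA of the apple pixels of a reflectance cube.

    No variance scaling is applied, so loadings stay in reflectance units.
    Scores satisfy ``score = (spectrum - mean) @ loading``.
    """
    if n_components > cube.shape[2]:
        raise ValueError("more components requested than bands")
    apple_mask = np.asarray(apple_mask, dtype=bool)
    if not apple_mask.any():
        raise ValueError("apple mask is empty")
    spectra = cube.data[apple_mask]
    if np.isnan(spectra).any():
        spectra = np.nan_to_num(spectra, nan=0.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(spectra)
    images = np.full((n_components,) + apple_mask.shape, np.nan)
    for k in range(n_components):
        images[k][apple_mask] = scores[:, k]
    return PCDecomposition(
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        score_images=images,
        mean_spectrum=pca.mean_,
        axis=cube.axis,
        apple_mask=apple_mask,
    )


@dataclass(frozen=True)
class LabeledPixels:
    """Selected pixel coordinates per class, with a purity audit."""

    bruise_yx: np.ndarray  # (n_b, 2) int
    sound_yx: np.ndarray   # (n_s, 2) int
    pc_index: int          # 1-based index of the score image used (0 = truth mode)
    bruise_purity: float   # fraction of selected bruise pixels inside truth
    sound_purity: float


def _constrained_otsu(vals: np.ndarray, max_minority_fraction: float,
                      min_minority: int) -> float | None:
    """Between-class-variance-maximizing threshold with a small minority side.

    Plain Otsu tends to bisect the dominant (sound) mode when the bruise
    occupies only a few percent of the apple; restricting the candidate
    thresholds to those that leave at most ``max_minority_fraction`` of the
    pixels on the minority side keeps the split on the bruise tail.
    """
    v = np.sort(vals)
    n = v.size
    cum = np.cumsum(v)
    total = cum[-1]
    k = np.arange(1, n)                # split sizes of the low side
    m0 = cum[:-1] / k
    m1 = (total - cum[:-1]) / (n - k)
    between = (k / n) * ((n - k) / n) * (m0 - m1) ** 2
    minority = np.minimum(k, n - k)
    allowed = (minority >= min_minority) & (minority <= max_minority_fraction * n)
    if not allowed.any():
        return None
    best = np.flatnonzero(allowed)[np.argmax(between[allowed])]
    return 0.5 * (v[best] + v[best + 1])


def _threshold_select(score: np.ndarray, mask: np.ndarray, margin_sds: float,
                      max_minority_fraction: float = 0.12,
                      min_minority: int = 10,
                      ) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Split a score image over ``mask``; minority side = bruise.

    Pixels within ``margin_sds`` within-mask standard deviations of the
    threshold are discarded from both classes (only clearly separated
    pixels are kept).  Returns the two coordinate sets plus the split
    quality (between-class variance over total variance, in [0, 1]), or
    None if either class ends up empty.
    """
    vals = score[mask]
    if not np.isfinite(vals).all() or vals.min() == vals.max():
        return None
    thr = _constrained_otsu(vals, max_minority_fraction, min_minority)
    if thr is None:
        return None
    hi = mask & (score > thr)
    lo = mask & (score <= thr)
    bruise_side, sound_side = (hi, lo) if hi.sum() <= lo.sum() else (lo, hi)
    w1 = bruise_side.sum() / mask.sum()
    m0, m1 = score[sound_side].mean(), score[bruise_side].mean()
    quality = float(w1 * (1 - w1) * (m1 - m0) ** 2 / max(vals.var(), 1e-30))
    margin = margin_sds * vals.std()
    bruise = bruise_side & (np.abs(score - thr) >= margin)
    sound = sound_side & (np.abs(score - thr) >= margin)
    if not bruise.any() or not sound.any():
        return None
    return np.argwhere(bruise), np.argwhere(sound), quality


def select_label_pixels(pc: PCDecomposition,
                        truth: SceneTruth | None = None,
                        mode: str = "threshold",
                        pc_index: int = 3,
                        fallback_pc_index: int = 4,
                        margin_sds: float = 1.05,
                        max_per_class: int = 60,
                        seed: int = 0) -> LabeledPixels:
    """Pick clearly-bruised and clearly-sound pixel coordinates.

    ``mode='threshold'`` thresholds the designated PC score image (default
    PC3, falling back to PC4 when PC3 yields no usable split); labels are
    audited against ``truth`` when available and the class purities are
    reported.  ``mode='truth'`` takes the classes straight from the ground
    truth (sound pixels away from the bruise boundary).  Both classes are
    subsampled to ``max_per_class`` pixels.
    """
    rng = np.random.default_rng(seed)
    mask = pc.apple_mask

    if mode == "truth":
        if truth is None:
            raise ValueError("truth mode needs a SceneTruth")
        from scipy.ndimage import binary_dilation

        bruise = truth.bruise_mask & mask
        guard = binary_dilation(truth.bruise_mask, iterations=3)
        sound = mask & ~guard
        if not sound.any():
            raise ValueError("no sound pixels outside the bruise guard band")
        bruise_yx, sound_yx = np.argwhere(bruise), np.argwhere(sound)
        used = 0
    elif mode == "threshold":
        picked = None
        for used in (pc_index, fallback_pc_index):
            if used > pc.score_images.shape[0]:
                continue
            picked = _threshold_select(pc.score_images[used - 1], mask, margin_sds)
            if picked is not None:
                break
        if picked is None:
            raise ValueError(
                "score thresholding produced an empty class on every "
                "designated PC image"
            )
        bruise_yx, sound_yx, _ = picked
    else:
        raise ValueError(f"unknown mode {mode!r}")

    def subsample(yx: np.ndarray) -> np.ndarray:
        if len(yx) > max_per_class:
            yx = yx[rng.choice(len(yx), max_per_class, replace=False)]
        return yx

    bruise_yx, sound_yx = subsample(bruise_yx), subsample(sound_yx)

    def purity(yx: np.ndarray, target: np.ndarray) -> float:
        if truth is None or len(yx) == 0:
            return float("nan")
        return float(target[yx[:, 0], yx[:, 1]].mean())

    return LabeledPixels(
        bruise_yx=bruise_yx,
        sound_yx=sound_yx,
        pc_index=used,
        bruise_purity=purity(bruise_yx, truth.bruise_mask) if truth else float("nan"),
        sound_purity=purity(sound_yx, ~truth.bruise_mask) if truth else float("nan"),
    )


# --------------------------------------------------------------------------
# dataset container and splitting
# --------------------------------------------------------------------------

@dataclass
class PixelSpectraDataset:
    """Labeled reflectance spectra with provenance and a train/test split."""

    spectra: np.ndarray           # (n, bands)
    labels: np.ndarray            # (n,) str, 'bruise' or 'sound'
    axis: SpectralAxis
    provenance: pd.DataFrame      # columns: apple_id, y, x, severity
    split: np.ndarray | None = None  # (n,) str, 'train' or 'test'

    @property
    def n(self) -> int:
        return len(self.labels)

    def partition(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        if self.split is None:
            raise ValueError("dataset has not been split yet")
        m = self.split == which
        return self.spectra[m], self.labels[m]

    def to_frame(self) -> pd.DataFrame:
        """One row per pixel: provenance, label, split, then wavelengths."""
        df = self.provenance.copy()
        df["label"] = self.labels
        df["split"] = self.split if self.split is not None else "unsplit"
        bands = pd.DataFrame(
            self.spectra,
            columns=[f"{wl:.1f}nm" for wl in self.axis.wavelengths_nm],
            index=df.index,
        )
        return pd.concat([df, bands], axis=1)


def split_dataset(ds: PixelSpectraDataset, train_fraction: float = 0.70,
                  seed: int = 0) -> PixelSpectraDataset:
    """Stratified train/test split (by class label), reproducible by seed."""
    classes = np.unique(ds.labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present before splitting")
    if ds.n < 10:
        raise ValueError("too few pixels to split")
    idx = np.arange(ds.n)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=ds.labels, random_state=seed
    )
    split = np.full(ds.n, "test", dtype=object)
    split[train_idx] = "train"
    ds.split = split.astype(str)
    return ds


def extract_cohort_dataset(scenes: list[Scene],
                           cubes: list[ReflectanceCube],
                           mode: str = "threshold",
                           max_per_class: int = 60,
                           seed: int = 0) -> PixelSpectraDataset:
    """Build the pooled labeled dataset from a calibrated cohort.

    Apples from bruised severity groups contribute both classes via
    :func:`select_label_pixels`; apples from the sound control group
    contribute sound pixels only (their severity label is known from the
    experimental design, not from the image).  Spectra are read from the
    calibrated reflectance cubes at the selected coordinates.
    """
    rows, spectra, labels = [], [], []
    rng = np.random.default_rng(seed)
    for apple_id, (scene, cube) in enumerate(zip(scenes, cubes)):
        mask = scene.truth.apple_mask
        if scene.effect.is_bruised:
            pc = pca_cube(cube, mask, n_components=4)
            picked = select_label_pixels(
                pc, truth=scene.truth, mode=mode,
                max_per_class=max_per_class,
                seed=int(rng.integers(2**31)),
            )
            groups = (("bruise", picked.bruise_yx), ("sound", picked.sound_yx))
        else:
            yx = np.argwhere(mask)
            if len(yx) > max_per_class:
                yx = yx[rng.choice(len(yx), max_per_class, replace=False)]
            groups = (("sound", yx),)
        for label, yx in groups:
            for y, x in yx:
                spectra.append(cube.data[y, x])
                labels.append(label)
                rows.append(
                    dict(apple_id=apple_id, y=int(y), x=int(x),
                         severity=scene.effect.severity_level)
                )
    return PixelSpectraDataset(
        spectra=np.asarray(spectra),
        labels=np.asarray(labels, dtype=object).astype(str),
        axis=scenes[0].raw.axis,
        provenance=pd.DataFrame(rows),
    )
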