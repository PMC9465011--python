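"""End-to-end study drivers shared by the analysis scripts and tests.

Two studies are wired here.  The key-wavelength study calibrates a cohort,
extracts the labeled pixel-spectra dataset, pre-selects candidate
wavelengths from pooled PCA loadings and runs SFS with the four
classifiers.  The resolution study takes the selected wavebands of one
classifier, enumerates exposure/bandwidth combinations, ranks them by
classification-map quality on the training cohort and evaluates the best
combination on a fresh cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import classification_maps as cmaps
from .band_selection import (
    CLASSIFIER_IDS,
    BandSelectionResult,
    CandidateWavelengths,
    SFSTrajectory,
    choose_optimal_count,
    preselect_candidates,
    run_sfs,
)
from .calibration import ReflectanceCube, flat_field
from .pixel_extraction import (
    PCDecomposition,
    PixelSpectraDataset,
    extract_cohort_dataset,
    split_dataset,
)
from .resolution_optimizer import (
    BinningCombination,
    CombinationScore,
    enumerate_combinations,
    evaluate_combination,
    score_combinations,
)
from .synthetic_data import CameraModel, Scene, generate_cohort

__all__ = [
    "calibrate_cohort",
    "pooled_pca",
    "KeyWavelengthStudy",
    "run_key_wavelength_study",
    "ResolutionStudy",
    "run_resolution_study",
]


def calibrate_cohort(scenes: list[Scene]) -> list[ReflectanceCube]:
    """Flat-field every scene against its own white/dark references."""
    return [flat_field(s.raw, s.white, s.dark) for s in scenes]


def pooled_pca(ds: PixelSpectraDataset, n_components: int = 4) -> PCDecomposition:
    """Mean-centered PCA of the pooled extracted spectra (loadings + variance)."""
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(ds.spectra)
    images = scores.T[:, :, None]  # pooled "score image": one column per component
    return PCDecomposition(
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        score_images=images,
        mean_spectrum=pca.mean_,
        axis=ds.axis,
        apple_mask=np.ones((scores.shape[0], 1), dtype=bool),
    )


@dataclass
class KeyWavelengthStudy:
    scenes: list[Scene]
    cubes: list[ReflectanceCube]
    dataset: PixelSpectraDataset
    pooled: PCDecomposition
    candidates: CandidateWavelengths
    selection: BandSelectionResult

    @property
    def cumulative_variance_pc1_4(self) -> float:
        return float(self.pooled.explained_variance_ratio[:4].sum())

    def test_accuracy_at(self, classifier_id: str, k: int) -> float:
        return self.selection.trajectories[classifier_id].test_accuracy[k - 1]


def run_key_wavelength_study(seed: int = 1, n_per_group: int = 6,
                             k_max: int = 5, folds: int = 5,
                             scenes: list[Scene] | None = None,
                             ) -> KeyWavelengthStudy:
    """Cohort -> calibration -> pixel dataset -> PCA pre-selection -> SFS."""
    if scenes is None:
        scenes = generate_cohort(n_per_group, seed=seed)
    cubes = calibrate_cohort(scenes)
    ds = extract_cohort_dataset(scenes, cubes, seed=seed)
    ds = split_dataset(ds, 0.70, seed=seed)
    pooled = pooled_pca(ds)
    candidates = preselect_candidates(pooled)
    trajectories: dict[str, SFSTrajectory] = {}
    for cid in CLASSIFIER_IDS:
        trajectories[cid] = run_sfs(ds, candidates.pooled_nm, cid,
                                    k_max=k_max, folds=folds, seed=seed)
    k_opt, warn = choose_optimal_count(trajectories)
    selection = BandSelectionResult(k_opt, warn, trajectories)
    return KeyWavelengthStudy(scenes, cubes, ds, pooled, candidates, selection)


@dataclass
class ResolutionStudy:
    combinations: dict[str, list[BinningCombination]]  # per classifier
    skipped: dict[str, list[str]]
    scores: dict[str, list[CombinationScore]]
    best_classifier: str
    best: BinningCombination
    evaluation: cmaps.DetectionReport


def run_resolution_study(study: KeyWavelengthStudy,
                         classifier_ids: tuple[str, ...] | str = CLASSIFIER_IDS,
                         eval_seed: int = 2, n_per_group: int = 6,
                         camera: CameraModel | None = None, seed: int = 1,
                         eval_scenes: list[Scene] | None = None,
                         ) -> ResolutionStudy:
    """Enumerate, rank and evaluate binning combinations.

    For each classifier the combinations are built on its own selected
    key wavebands (reference = selected band nearest 553.9 nm) and ranked
    on the key-wavelength study's own (training) cohort; the overall best
    (classifier, combination) pair under the lexicographic rule is then
    applied to a freshly generated cohort and scored apple by apple
    against ground truth.
    """
    if isinstance(classifier_ids, str):
        classifier_ids = (classifier_ids,)
    camera = camera or CameraModel()
    axis = study.dataset.axis
    all_combos: dict[str, list[BinningCombination]] = {}
    all_skipped: dict[str, list[str]] = {}
    all_scores: dict[str, list[CombinationScore]] = {}
    ranked: list[tuple[tuple, str, BinningCombination]] = []
    for cid in classifier_ids:
        bands = study.selection.key_wavelengths(cid)
        ref = min(bands, key=lambda w: abs(w - 553.9))
        combos, skipped = enumerate_combinations(camera, axis, tuple(bands),
                                                 reference_center_nm=ref)
        all_combos[cid], all_skipped[cid] = combos, skipped
        if not combos:
            all_scores[cid] = []
            continue
        scores, _ = score_combinations(combos, study.scenes, cid,
                                       study.dataset, camera, seed=seed)
        all_scores[cid] = scores
        for s in scores:
            if not s.flagged:
                ranked.append(((s.apple_accuracy, -s.false_positive_pixels,
                                -s.combination.exposure_s), cid, s.combination))
    if not ranked:
        raise ValueError("no feasible binning combination for any classifier")
    _, best_cid, best = max(ranked, key=lambda r: r[0])
    if eval_scenes is None:
        eval_scenes = generate_cohort(n_per_group, seed=eval_seed)
    report = evaluate_combination(best, eval_scenes, best_cid,
                                  study.dataset, camera, seed=seed + 1)
    if report is None:
        raise ValueError("best combination has degenerate binned features")
    return ResolutionStudy(all_combos, all_skipped, all_scores, best_cid, best,
                           report)
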