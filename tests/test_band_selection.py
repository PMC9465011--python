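"""Candidate pre-selection, SFS oracle checks and the plateau rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bruisebands import SpectralAxis
from bruisebands.band_selection import (
    CLASSIFIER_IDS,
    SFSTrajectory,
    _cv_accuracy,
    choose_optimal_count,
    make_classifier,
    preselect_candidates,
    run_sfs,
)
from bruisebands.pixel_extraction import PCDecomposition, PixelSpectraDataset


def _pc_from_loadings(loadings, axis):
    loadings = np.asarray(loadings, dtype=float)
    k = loadings.shape[1]
    return PCDecomposition(
        loadings=loadings,
        explained_variance_ratio=np.full(k, 1.0 / k),
        score_images=np.zeros((k, 1, 1)),
        mean_spectrum=np.zeros(loadings.shape[0]),
        axis=axis,
        apple_mask=np.ones((1, 1), bool),
    )


class TestPreselect:
    def test_single_gaussian_bump_gives_one_candidate_at_center(self):
        axis = SpectralAxis(np.linspace(400, 1000, 61))
        lam = axis.wavelengths_nm
        bump = np.exp(-(((lam - 700.0) / 40.0) ** 2))
        cand = preselect_candidates(_pc_from_loadings(bump[:, None], axis),
                                    n_components=1)
        assert cand.pooled_nm.tolist() == [700.0]
        assert cand.per_pc[1] == [(700.0, "peak")]

    def test_sine_loading_yields_alternating_extrema(self):
        axis = SpectralAxis(np.linspace(400, 1000, 121))
        lam = axis.wavelengths_nm
        sine = np.sin(2 * np.pi * (lam - 400) / 200.0)  # 3 peaks, 3 valleys
        cand = preselect_candidates(_pc_from_loadings(sine[:, None], axis),
                                    n_components=1)
        kinds = [k for _, k in cand.per_pc[1]]
        assert kinds == ["peak", "valley"] * (len(kinds) // 2)
        assert len(cand.pooled_nm) == len(kinds)

    def test_constant_loading_contributes_nothing(self):
        axis = SpectralAxis(np.linspace(400, 1000, 31))
        lam = axis.wavelengths_nm
        bump = np.exp(-(((lam - 600.0) / 50.0) ** 2))
        loadings = np.stack([bump, np.full_like(lam, 0.3)], axis=1)
        cand = preselect_candidates(_pc_from_loadings(loadings, axis),
                                    n_components=2)
        assert cand.per_pc[2] == []
        assert cand.pooled_nm.tolist() == [600.0]

    def test_all_constant_loadings_rejected(self):
        axis = SpectralAxis(np.linspace(400, 1000, 31))
        loadings = np.zeros((31, 2))
        with pytest.raises(ValueError, match="no candidate"):
            preselect_candidates(_pc_from_loadings(loadings, axis), n_components=2)

    def test_default_cohort_candidates_include_key_wavebands(self, study):
        pooled = study.candidates.pooled_nm
        step = study.dataset.axis.sampling_interval_nm
        for key in (424.5, 553.9, 774.2, 812.5):
            assert np.min(np.abs(pooled - key)) <= 0.5 * step + 1e-9, key


def _gaussian_dataset(n=160, n_features=6, informative=2, sep=2.5, seed=0):
    """Two-class Gaussian toy set where only one feature carries signal."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, (n, n_features))
    y = np.array(["sound", "bruise"] * (n // 2))
    X[y == "bruise", informative] += sep
    axis = SpectralAxis(np.linspace(400, 1000, n_features))
    split = np.array(["train"] * (7 * n // 10) + ["test"] * (n - 7 * n // 10))
    rng.shuffle(split)
    return PixelSpectraDataset(
        spectra=X, labels=y, axis=axis,
        provenance=pd.DataFrame({"apple_id": np.zeros(n, int),
                                 "y": np.zeros(n, int), "x": np.zeros(n, int),
                                 "severity": ["?"] * n}),
        split=split,
    )


class TestRunSfs:
    @pytest.mark.parametrize("classifier_id", CLASSIFIER_IDS)
    def test_first_pick_matches_single_feature_brute_force(self, classifier_id):
        ds = _gaussian_dataset()
        cand = ds.axis.wavelengths_nm
        traj = run_sfs(ds, cand, classifier_id, k_max=2, seed=0)
        # oracle: exhaustive CV accuracy of every single feature
        X, y = ds.partition("train")
        accs = {nm: _cv_accuracy(classifier_id, X[:, [j]], y, 5, 0)
                for j, nm in enumerate(cand)}
        best = min((nm for nm in cand
                    if accs[nm] == max(accs.values())))
        assert traj.selected_nm[0] == best
        assert traj.selected_nm[0] == ds.axis.wavelengths_nm[2]  # the planted one

    def test_all_noise_candidates_stay_near_chance(self):
        ds = _gaussian_dataset(sep=0.0, seed=3)
        traj = run_sfs(ds, ds.axis.wavelengths_nm, "LDA", k_max=3, seed=0)
        n_train = int((ds.split == "train").sum())
        ci = 3.0 * np.sqrt(0.25 / n_train)  # 3-sigma binomial interval
        assert all(abs(a - 0.5) < ci + 0.05 for a in traj.cv_accuracy)

    def test_selection_is_nested_and_deterministic(self):
        ds = _gaussian_dataset(seed=5)
        a = run_sfs(ds, ds.axis.wavelengths_nm, "QDA", k_max=4, seed=9)
        b = run_sfs(ds, ds.axis.wavelengths_nm, "QDA", k_max=4, seed=9)
        assert a.selected_nm == b.selected_nm
        assert a.cv_accuracy == b.cv_accuracy
        for k in range(1, 4):
            assert set(a.selected_at(k)) < set(a.selected_at(k + 1))

    def test_exhaustive_best_pair_at_least_matches_greedy_pair(self):
        ds = _gaussian_dataset(n_features=6, seed=7)
        cand = ds.axis.wavelengths_nm
        traj = run_sfs(ds, cand, "LDA", k_max=2, seed=1)
        X, y = ds.partition("train")
        idx = {nm: j for j, nm in enumerate(cand)}
        best_pair = max(
            _cv_accuracy("LDA", X[:, [idx[a], idx[b]]], y, 5, 1)
            for a, b in itertools.combinations(cand, 2)
        )
        assert best_pair >= traj.cv_accuracy[1] - 1e-12

    def test_unknown_classifier_rejected(self):
        ds = _gaussian_dataset()
        with pytest.raises(ValueError, match="classifier"):
            run_sfs(ds, ds.axis.wavelengths_nm, "RandomForest")

    def test_too_few_candidates_rejected(self):
        ds = _gaussian_dataset()
        with pytest.raises(ValueError, match="k_max"):
            run_sfs(ds, ds.axis.wavelengths_nm[:2], "LDA", k_max=5)


class TestPlantedStructureRecovery:
    def test_selections_cover_the_planted_regions_across_replicates(self):
        """The union of the four classifiers' 3-band picks finds the bruise
        signature regions (blue brown-pigment, browning band, NIR water
        plateau) in at least 9 of 10 replicate cohorts."""
        import itertools
        import warnings

        from bruisebands.workflow import run_key_wavelength_study

        regions = {"blue": (400, 470), "brown": (525, 610), "nir": (740, 1000)}
        hits = 0
        for seed in range(10):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                st = run_key_wavelength_study(seed=seed, n_per_group=3)
            union = set(itertools.chain.from_iterable(
                st.selection.trajectories[c].selected_at(3)
                for c in CLASSIFIER_IDS))
            step = st.dataset.axis.sampling_interval_nm
            hits += all(
                any(lo - step <= nm <= hi + step for nm in union)
                for lo, hi in regions.values()
            )
        assert hits >= 9


class TestChooseOptimalCount:
    def _traj(self, accs):
        return SFSTrajectory("LDA", list(range(len(accs))), list(accs),
                             list(accs))

    def test_plateau_after_three_bands(self):
        accs = [0.90, 0.95, 0.96, 0.961, 0.962]
        trajs = {c: self._traj(accs) for c in CLASSIFIER_IDS}
        assert choose_optimal_count(trajs) == (3, False)

    def test_monotone_gains_return_k_max_with_warning(self):
        accs = [0.5, 0.6, 0.7, 0.8, 0.9]
        trajs = {c: self._traj(accs) for c in CLASSIFIER_IDS}
        assert choose_optimal_count(trajs) == (5, True)

    def test_floor_blocks_early_plateau(self):
        # flat but below the accuracy floor until k=3
        accs = [0.90, 0.905, 0.95, 0.951, 0.951]
        trajs = {c: self._traj(accs) for c in CLASSIFIER_IDS}
        assert choose_optimal_count(trajs) == (3, False)

    def test_single_lagging_classifier_controls_the_count(self):
        fast = [0.95, 0.96, 0.961, 0.962, 0.962]
        slow = [0.80, 0.90, 0.95, 0.952, 0.953]
        trajs = {c: self._traj(fast) for c in CLASSIFIER_IDS}
        trajs["QDA"] = self._traj(slow)
        assert choose_optimal_count(trajs) == (3, False)


class TestClassifierFactory:
    def test_qda_regularizes_only_when_singular(self, rng):
        X = rng.normal(size=(40, 2))
        X[:, 1] = X[:, 0]  # collinear -> singular class covariance
        y = np.array(["a", "b"] * 20)
        clf = make_classifier("QDA")
        clf.fit(X, y)
        assert clf.reg_param > 0
        clf2 = make_classifier("QDA")
        clf2.fit(rng.normal(size=(40, 2)), y)
        assert clf2.reg_param == 0.0

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_classifier("perceptron")
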