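"""Key-waveband selection: PCA pre-selection + sequential forward selection.

Candidate wavelengths are the peaks and valleys of the retained principal
component loadings (weighting coefficients): an extremum marks a wavelength
that contributes strongly to the linear transformation.  From that pool a
greedy sequential forward selection (SFS) adds one band at a time per
classifier, maximizing mean 5-fold cross-validated accuracy on the training
partition only; the held-out test partition is scored once per step for
reporting.  Four classifiers are supported: LDA, QDA, a linear-kernel SVM
and an RBF-kernel SVM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .pixel_extraction import PCDecomposition, PixelSpectraDataset

__all__ = [
    "CLASSIFIER_IDS",
    "CandidateWavelengths",
    "SFSTrajectory",
    "BandSelectionResult",
    "make_classifier",
    "preselect_candidates",
    "run_sfs",
    "choose_optimal_count",
]

CLASSIFIER_IDS = ("LDA", "QDA", "SVM", "SVM-RBF")


# --------------------------------------------------------------------------
# classifiers
# --------------------------------------------------------------------------

def _median_heuristic_gamma(X: np.ndarray, rng_seed: int = 0,
                            max_points: int = 500) -> float:
    """RBF kernel width 1/(2 m^2) with m the median pairwise distance."""
    rng = np.random.default_rng(rng_seed)
    if len(X) > max_points:
        X = X[rng.choice(len(X), max_points, replace=False)]
    d = pairwise_distances(X)
    m = np.median(d[np.triu_indices_from(d, k=1)])
    if not np.isfinite(m) or m <= 0:
        return 1.0
    return 1.0 / (2.0 * m**2)


class _RobustQDA(QuadraticDiscriminantAnalysis):
    """QDA that regularizes the class covariances only when one is singular."""

    def fit(self, X, y):
        try:
            return super().fit(X, y)
        except np.linalg.LinAlgError:
            self.reg_param = 1e-3
            return super().fit(X, y)


def make_classifier(classifier_id: str, X_train: np.ndarray | None = None):
    """Classifier with the package's standard hyperparameters.

    SVMs are wrapped in a standardizing pipeline (scale-sensitive); the
    discriminant analyses run on raw reflectance (affine-equivariant).
    The RBF width follows the median heuristic on standardized training
    data when ``X_train`` is given.
    """
    if classifier_id == "LDA":
        return LinearDiscriminantAnalysis()
    if classifier_id == "QDA":
        return _RobustQDA(reg_param=0.0)
    if classifier_id == "SVM":
        return Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="linear", C=1.0))]
        )
    if classifier_id == "SVM-RBF":
        gamma = "scale"
        if X_train is not None:
            gamma = _median_heuristic_gamma(StandardScaler().fit_transform(X_train))
        return Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", C=1.0, gamma=gamma))]
        )
    raise ValueError(f"unknown classifier id {classifier_id!r}")


# --------------------------------------------------------------------------
# PCA pre-selection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateWavelengths:
    """Dominant wavelengths per PC and the pooled deduplicated list."""

    per_pc: dict[int, list[tuple[float, str]]]  # pc (1-based) -> (nm, 'peak'|'valley')
    pooled_nm: np.ndarray                       # sorted unique wavelengths


def preselect_candidates(pc: PCDecomposition, n_components: int = 4,
                         prominence_fraction: float = 0.10) -> CandidateWavelengths:
    """Local extrema of the first ``n_components`` loadings.

    An extremum qualifies if its prominence exceeds
    ``prominence_fraction * max(|loading|)`` for that component; a constant
    loading simply contributes nothing.
    """
    if pc.loadings.shape[1] < n_components:
        raise ValueError("decomposition has fewer components than requested")
    lam = pc.axis.wavelengths_nm
    per_pc: dict[int, list[tuple[float, str]]] = {}
    pool: list[float] = []
    for k in range(n_components):
        v = pc.loadings[:, k]
        scale = np.abs(v).max()
        found: list[tuple[float, str]] = []
        if scale > 0:
            prom = prominence_fraction * scale
            for sign, tag in ((1.0, "peak"), (-1.0, "valley")):
                idx, _ = find_peaks(sign * v, prominence=prom)
                found.extend((float(lam[i]), tag) for i in idx)
        per_pc[k + 1] = sorted(found)
        pool.extend(nm for nm, _ in found)
    pooled = np.unique(np.asarray(pool))
    if pooled.size == 0:
        raise ValueError("no candidate wavelengths found in any loading")
    return CandidateWavelengths(per_pc=per_pc, pooled_nm=pooled)


# --------------------------------------------------------------------------
# sequential forward selection
# --------------------------------------------------------------------------

@dataclass
class SFSTrajectory:
    classifier_id: str
    selected_nm: list[float]          # in selection order
    cv_accuracy: list[float]          # mean CV accuracy after each addition
    test_accuracy: list[float]        # held-out accuracy after each addition

    def selected_at(self, k: int) -> list[float]:
        return self.selected_nm[:k]


@dataclass
class BandSelectionResult:
    optimal_count: int
    warning: bool
    trajectories: dict[str, SFSTrajectory]

    def key_wavelengths(self, classifier_id: str) -> list[float]:
        return self.trajectories[classifier_id].selected_at(self.optimal_count)


def _cv_accuracy(classifier_id: str, X: np.ndarray, y: np.ndarray,
                 folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, va in skf.split(X, y):
        clf = make_classifier(classifier_id, X[tr])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[va]) == y[va])))
    return float(np.mean(accs))


def run_sfs(ds: PixelSpectraDataset, candidates_nm: np.ndarray,
            classifier_id: str, k_max: int = 5, folds: int = 5,
            seed: int = 0) -> SFSTrajectory:
    """Greedy forward selection over the candidate wavelengths.

    At each step the candidate maximizing mean ``folds``-fold CV accuracy on
    the training partition joins the selected set; ties break toward the
    lower wavelength.  The test partition is used for reporting only.
    """
    if classifier_id not in CLASSIFIER_IDS:
        raise ValueError(f"unknown classifier id {classifier_id!r}")
    candidates_nm = np.sort(np.asarray(candidates_nm, dtype=float))
    if candidates_nm.size < k_max:
        raise ValueError("need at least k_max candidate wavelengths")
    cols = {nm: ds.axis.index_of(nm, tol_nm=np.inf) for nm in candidates_nm}
    X_tr, y_tr = ds.partition("train")
    X_te, y_te = ds.partition("test")
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training partition is single-class")

    selected: list[float] = []
    cv_curve: list[float] = []
    test_curve: list[float] = []
    remaining = list(candidates_nm)
    for _ in range(k_max):
        best_nm, best_acc = None, -np.inf
        for nm in remaining:  # ascending -> ties keep the lower wavelength
            feat = [cols[s] for s in selected] + [cols[nm]]
            acc = _cv_accuracy(classifier_id, X_tr[:, feat], y_tr, folds, seed)
            if acc > best_acc + 1e-12:
                best_nm, best_acc = nm, acc
        selected.append(best_nm)
        remaining.remove(best_nm)
        cv_curve.append(best_acc)
        feat = [cols[s] for s in selected]
        clf = make_classifier(classifier_id, X_tr[:, feat])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X_tr[:, feat], y_tr)
            test_curve.append(float(np.mean(clf.predict(X_te[:, feat]) == y_te)))
    return SFSTrajectory(classifier_id, selected, cv_curve, test_curve)


def choose_optimal_count(trajectories: dict[str, SFSTrajectory],
                         epsilon: float = 0.01,
                         accuracy_floor: float = 0.94) -> tuple[int, bool]:
    """Smallest band count after which no classifier improves meaningfully.

    Returns the smallest ``k`` such that every classifier's CV accuracy at
    ``k`` meets ``accuracy_floor`` and gains less than ``epsilon`` from
    ``k`` to ``k+1``.  If no such ``k`` exists, returns ``k_max`` with the
    warning flag set.
    """
    curves = [t.cv_accuracy for t in trajectories.values()]
    k_max = min(len(c) for c in curves)
    for k in range(1, k_max):
        ok = all(
            c[k - 1] >= accuracy_floor and (c[k] - c[k - 1]) < epsilon
            for c in curves
        )
        if ok:
            return k, False
    return k_max, True
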