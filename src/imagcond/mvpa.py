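"""ROI cross-classification with two-level permutation/bootstrap inference.

CS+ vs CS− decoding with a linear support-vector machine trained on one
(phase, modality) trial set and tested on another.  Significance uses a
two-level resampling scheme: per participant, a null distribution of test
accuracies from classifiers retrained on label-permuted training data; at
the group level, a bootstrap that repeatedly draws one permuted accuracy per
participant (with replacement) and records the across-participant mean.  The
observed group-mean accuracy is compared one-sided (above chance) to the
group null with the add-one empirical p estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .glm import PatternDataset

__all__ = [
    "CrossClassSpec",
    "ClassificationResult",
    "GroupResult",
    "select_features",
    "cross_classify",
    "participant_null",
    "group_bootstrap_null",
    "empirical_p",
    "run_cross_classification",
    "DegenerateLabelsError",
]

SVM_C = 1.0  # fixed regularization for the linear SVM


class DegenerateLabelsError(ValueError):
    pass


@dataclass(frozen=True)
class CrossClassSpec:
    """Train/test selectors and feature rule for one decoding analysis."""

    train_phase: str
    train_modality: str
    test_phase: str
    test_modality: str
    feature_rule: str = "all_roi_voxels"  # or "top_k_univariate"
    k: int = 300

    def __post_init__(self) -> None:
        if (self.train_phase, self.train_modality) == (self.test_phase, self.test_modality):
            raise ValueError("train and test selectors must draw disjoint trial sets")
        if self.feature_rule not in ("all_roi_voxels", "top_k_univariate"):
            raise ValueError(f"unknown feature rule {self.feature_rule!r}")

    @property
    def name(self) -> str:
        return (
            f"{self.train_phase}:{self.train_modality}->"
            f"{self.test_phase}:{self.test_modality}"
        )


def select_features(
    train_patterns: PatternDataset | np.ndarray, rule: str, k: int = 300
) -> np.ndarray:
    """Voxel indices to use, computed on TRAINING data only.

    ``top_k_univariate`` keeps the k voxels with the largest mean absolute
    beta across training trials; ties break to the lowest index.
    """
    X = train_patterns.X if isinstance(train_patterns, PatternDataset) else np.asarray(train_patterns)
    n_voxels = X.shape[1]
    if rule == "all_roi_voxels":
        return np.arange(n_voxels)
    if rule != "top_k_univariate":
        raise ValueError(f"unknown feature rule {rule!r}")
    if k < 1 or k > n_voxels:
        raise ValueError(f"k={k} out of range for {n_voxels} voxels")
    scores = np.abs(X).mean(axis=0)
    order = np.argsort(-scores, kind="stable")  # stable → ties keep low index
    return np.sort(order[:k])


try:  # low-level libsvm entry points: same solver as SVC, far less call overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover - fallback for other sklearn builds
    _libsvm = None


class _PrecomputedLinearSVM:
    """Linear SVM via a precomputed Gram matrix.

    Computing the train and test Gram matrices once lets permutation loops
    refit on permuted labels without touching voxel space again; the
    estimator is identical to SVC(kernel="linear", C=SVM_C).  When available,
    the raw libsvm fit/predict routines are called directly — the same C
    solver SVC wraps, minus the per-call validation overhead that dominates
    at 10 000-permutation scale; ``use_fast_path=False`` forces the public
    SVC route (the two agree exactly; see the test suite).
    """

    def __init__(
        self,
        X_train: np.ndarray,
        X_test: np.ndarray,
        C: float = SVM_C,
        use_fast_path: bool = True,
    ):
        self.K_train = np.ascontiguousarray(X_train @ X_train.T, dtype=np.float64)
        self.K_test = np.ascontiguousarray(X_test @ X_train.T, dtype=np.float64)
        self.C = C
        self.fast = use_fast_path and _libsvm is not None

    def accuracy(self, y_train: np.ndarray, y_test: np.ndarray) -> float:
        if self.fast:
            model = _libsvm.fit(
                self.K_train,
                np.asarray(y_train, dtype=np.float64),
                svm_type=0,
                kernel="precomputed",
                C=self.C,
            )
            pred = _libsvm.predict(self.K_test, *model[:7], svm_type=0, kernel="precomputed")
        else:
            clf = SVC(kernel="precomputed", C=self.C)
            clf.fit(self.K_train, y_train)
            pred = clf.predict(self.K_test)
        return float(np.mean(pred == y_test))


def _prepare(train: PatternDataset, test: PatternDataset, spec: CrossClassSpec):
    y_train, y_test = train.y(), test.y()
    if len(np.unique(y_train)) < 2:
        raise DegenerateLabelsError("training set contains a single class")
    if len(y_test) == 0:
        raise ValueError("empty test set")
    voxels = select_features(train, spec.feature_rule, spec.k)
    svm = _PrecomputedLinearSVM(train.X[:, voxels], test.X[:, voxels])
    return svm, y_train, y_test


def cross_classify(train: PatternDataset, test: PatternDataset, spec: CrossClassSpec) -> float:
    """Observed test accuracy for one participant."""
    svm, y_train, y_test = _prepare(train, test, spec)
    return svm.accuracy(y_train, y_test)


def participant_null(
    train: PatternDataset,
    test: PatternDataset,
    spec: CrossClassSpec,
    n_perm: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Test accuracies after uniform random permutation of training labels.

    Test labels are untouched; the classifier is retrained each iteration.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if hasattr(seed, "permutation") else np.random.default_rng(seed)
    svm, y_train, y_test = _prepare(train, test, spec)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = svm.accuracy(rng.permutation(y_train), y_test)
    return null


def group_bootstrap_null(
    per_participant_nulls: Sequence[np.ndarray] | np.ndarray,
    n_boot: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Bootstrap group-mean accuracies: one draw per participant per iteration."""
    nulls = np.asarray(per_participant_nulls, dtype=float)
    if nulls.ndim != 2 or nulls.shape[0] < 2 or nulls.shape[1] < 1:
        raise ValueError("need >= 2 participants with equal-length, non-empty nulls")
    rng = seed if hasattr(seed, "integers") else np.random.default_rng(seed)
    n_participants, n_perm = nulls.shape
    idx = rng.integers(0, n_perm, size=(n_boot, n_participants))
    return nulls[np.arange(n_participants), idx].mean(axis=1)


def empirical_p(observed_group_mean: float, group_null: np.ndarray) -> float:
    """One-sided (above chance) add-one empirical p-value."""
    group_null = np.asarray(group_null)
    if group_null.size == 0:
        raise ValueError("empty group null")
    return float((1 + np.sum(group_null >= observed_group_mean)) / (1 + group_null.size))


@dataclass
class ClassificationResult:
    participant_id: str
    accuracy: float


@dataclass
class GroupResult:
    """Group-level outcome of one cross-classification analysis."""

    spec: CrossClassSpec
    per_participant: pd.Series  # participant_id → accuracy
    group_null: np.ndarray
    n_perm: int
    n_boot: int
    seed: int

    @property
    def group_mean(self) -> float:
        return float(self.per_participant.mean())

    @property
    def p_value(self) -> float:
        return empirical_p(self.group_mean, self.group_null)

    def summary(self) -> dict:
        return {
            "analysis": self.spec.name,
            "group_mean_accuracy": self.group_mean,
            "p_value": self.p_value,
            "null_mean": float(self.group_null.mean()),
            "n_participants": int(len(self.per_participant)),
            "n_perm": self.n_perm,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def run_cross_classification(
    datasets: Mapping[str, PatternDataset],
    spec: CrossClassSpec,
    n_perm: int,
    n_boot: int,
    seed: int,
) -> GroupResult:
    """Full two-level analysis over a cohort.

    ``datasets`` maps participant id → a PatternDataset containing the trials
    of both phases; train/test subsets are drawn by the spec's selectors.
    """
    ss = np.random.SeedSequence([int(seed), 7])
    children = ss.spawn(len(datasets) + 1)
    accuracies = {}
    nulls = []
    for child, (pid, ds) in zip(children, sorted(datasets.items())):
        train = ds.select(phase=spec.train_phase, modality=spec.train_modality)
        test = ds.select(phase=spec.test_phase, modality=spec.test_modality)
        accuracies[pid] = cross_classify(train, test, spec)
        nulls.append(participant_null(train, test, spec, n_perm, np.random.default_rng(child)))
    group_null = group_bootstrap_null(np.array(nulls), n_boot, np.random.default_rng(children[-1]))
    return GroupResult(
        spec=spec,
        per_participant=pd.Series(accuracies, name="accuracy"),
        group_null=group_null,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=int(seed),
    )


def load_roi_mask(path: str | Path) -> np.ndarray:
    """ROI voxel indices from a plain-text index list or a NIfTI mask."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        data = np.asarray(nib.load(str(path)).dataobj)
        return np.flatnonzero(data.ravel() > 0)
    return np.loadtxt(path, dtype=int, ndmin=1)
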