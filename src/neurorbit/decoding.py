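"""Population decoding of reach direction and target motion.

Single-trial population rates are soft-normalized and classified with a
linear multiclass support-vector machine (one-vs-one reduction of
binary maximum-margin classifiers), either in a 100 ms window sliding
at 50 ms steps with 10-fold cross-validation, or in the peri-movement
window with train/test splits drawn from different condition sets to
measure cross-condition transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .synth import PopulationActivity
from .geometry import soft_normalize

CHANCE = {"direction": 1.0 / 8.0, "velocity": 1.0 / 5.0}


@dataclass
class DecodingResult:
    window_centers: np.ndarray  # ms re alignment
    accuracy_mean: np.ndarray
    accuracy_sd: np.ndarray
    label_kind: str

    @property
    def chance(self) -> float:
        return CHANCE[self.label_kind]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_center_ms": self.window_centers,
                "accuracy_mean": self.accuracy_mean,
                "accuracy_sd": self.accuracy_sd,
                "chance": self.chance,
            }
        )


@dataclass
class TransferResult:
    train_label: str
    test_label: str
    accuracies: np.ndarray  # one per repetition

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std())


def _labels(activity: PopulationActivity, label_kind: str) -> np.ndarray:
    if label_kind == "direction":
        return activity.trial_table["sector"].to_numpy()
    if label_kind == "velocity":
        return activity.trial_table["target_velocity"].to_numpy()
    raise ValueError("label_kind must be 'direction' or 'velocity'")


def _svm() -> SVC:
    return SVC(kernel="linear", C=1.0)


def sliding_window_decode(
    activity: PopulationActivity,
    label_kind: str,
    window_ms: float = 100.0,
    step_ms: float = 50.0,
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
) -> DecodingResult:
    """Sliding-window cross-validated decoding accuracy.

    Per window the soft-normalized rates are averaged, and accuracy is
    the 10-fold cross-validated score of a linear SVM; mean and sd are
    over ``reps`` repetitions with re-randomized fold assignment.
    """
    y = _labels(activity, label_kind)
    classes, counts = np.unique(y, return_counts=True)
    short = classes[counts < folds]
    if short.size:
        raise ValueError(f"classes {short.tolist()} have fewer than {folds} trials")
    norm = soft_normalize(activity.rates)
    centers = activity.bin_centers
    starts = np.arange(centers.min(), centers.max() - window_ms + 1e-9, step_ms)
    win_centers, means, sds = [], [], []
    rng = np.random.default_rng(seed)
    for w0 in starts:
        mask = (centers >= w0) & (centers < w0 + window_ms)
        if not mask.any():
            continue
        X = norm[:, :, mask].mean(axis=2).T  # trials x neurons
        accs = []
        for _ in range(reps):
            cv = StratifiedKFold(folds, shuffle=True, random_state=int(rng.integers(2**31)))
            accs.append(cross_val_score(_svm(), X, y, cv=cv).mean())
        win_centers.append(w0 + window_ms / 2.0)
        means.append(np.mean(accs))
        sds.append(np.std(accs))
    return DecodingResult(np.asarray(win_centers), np.asarray(means), np.asarray(sds), label_kind)


def transfer_decode(
    activity: PopulationActivity,
    label_kind: str,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    n_train: int = 100,
    n_test: int = 100,
    reps: int = 1000,
    window_ms: tuple[float, float] = (-100.0, 100.0),
    seed: int = 0,
    train_label: str = "train",
    test_label: str = "test",
) -> TransferResult:
    """Cross-condition transfer decoding at the movement-onset window.

    Per repetition, ``n_train`` trials are sampled without replacement
    from the training condition set and ``n_test`` from the test set; a
    linear SVM fitted on the former is scored on the latter.
    """
    y = _labels(activity, label_kind)
    norm = soft_normalize(activity.rates)
    mask_t = (activity.bin_centers >= window_ms[0]) & (activity.bin_centers <= window_ms[1])
    X = norm[:, :, mask_t].mean(axis=2).T
    train_idx = np.flatnonzero(train_mask)
    test_idx = np.flatnonzero(test_mask)
    if train_idx.size < n_train or test_idx.size < n_test:
        raise ValueError(
            f"insufficient trials: train {train_idx.size}<{n_train} "
            f"or test {test_idx.size}<{n_test}"
        )
    rng = np.random.default_rng(seed)
    accs = np.empty(reps)
    for r in range(reps):
        tr = rng.choice(train_idx, n_train, replace=False)
        te = rng.choice(test_idx, n_test, replace=False)
        clf = _svm().fit(X[tr], y[tr])
        accs[r] = clf.score(X[te], y[te])
    return TransferResult(train_label, test_label, accs)


def standard_direction_transfers(
    activity: PopulationActivity,
    n_train: int = 100,
    n_test: int = 100,
    reps: int = 100,
    seed: int = 0,
) -> dict[str, TransferResult]:
    """The three reach-direction transfer contrasts: CCW vs CW,
    120 vs 240 deg/s, and static vs moving."""
    v = activity.trial_table["target_velocity"].to_numpy()
    contrasts = {
        "ccw_vs_cw": (v > 0, v < 0),
        "120_vs_240": (np.abs(v) == 120, np.abs(v) == 240),
        "static_vs_motion": (v == 0, v != 0),
    }
    out = {}
    for i, (name, (m_train, m_test)) in enumerate(contrasts.items()):
        out[name] = transfer_decode(
            activity, "direction", m_train, m_test,
            n_train=n_train, n_test=n_test, reps=reps, seed=seed + i,
            train_label=name.split("_vs_")[0], test_label=name.split("_vs_")[1],
        )
    return out


def compare_transfers(a: TransferResult, b: TransferResult) -> float:
    """One-tailed paired t-test p-value that ``a`` has lower accuracy
    than ``b`` over matched repetitions."""
    if a.accuracies.size != b.accuracies.size:
        raise ValueError("repetition counts differ")
    return float(stats.ttest_rel(a.accuracies, b.accuracies, alternative="less").pvalue)
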