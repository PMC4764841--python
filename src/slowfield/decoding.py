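"""Nested cross-validated movement decoding.

Two binary problems share one machinery:

* movement type (grasp vs open) from a single 500-ms feature window, where
  the window and the RBF-SVM hyperparameters (gamma, cost) are selected by
  inner cross-validation on the training trials only;
* movement intention (rest vs intention) from the concatenation of 11
  feature windows per epoch (rest: windows covering -2500..-1000 ms before
  the cue; intention: -500..+1000 ms around it).

Outer-fold test trials never influence window or hyperparameter selection;
ties in the inner selection break deterministically toward smaller cost,
then smaller gamma, then the earlier window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    IncompleteTableError,
    StratificationError,
    WindowBoundsError,
)

# cue-relative window ends (ms) of the two intention-task epochs: eleven
# 500-ms windows covering -2500..-1000 ms (rest) and -500..+1000 ms
# (intention), 100-ms hop, under the causal end-labelled convention
REST_EPOCH_ENDS = tuple(np.arange(-2000.0, -900.0, 100.0))
INTENTION_EPOCH_ENDS = tuple(np.arange(0.0, 1100.0, 100.0))
# window search range for the type task: 500-ms windows starting -500..+500
TYPE_SEARCH_ENDS = tuple(np.arange(0.0, 1100.0, 100.0))


@dataclass(frozen=True)
class LabeledFeatureSet:
    """Per-trial feature windows on a grid, with movement labels."""

    x: np.ndarray               # (n_trials, n_windows, n_channels)
    window_ends_ms: np.ndarray  # (n_windows,)
    labels: np.ndarray          # (n_trials,) str or int
    trial_ids: np.ndarray       # (n_trials,)

    def window_index(self, end_ms: float) -> int:
        idx = np.flatnonzero(np.isclose(self.window_ends_ms, end_ms))
        if idx.size != 1:
            raise WindowBoundsError(
                f"window end {end_ms} ms not on the feature grid"
            )
        return int(idx[0])

    def with_labels(self, labels) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            x=self.x, window_ends_ms=self.window_ends_ms,
            labels=np.asarray(labels), trial_ids=self.trial_ids,
        )


def feature_set_from_session(session, stats, grid, kind="smf"):
    from .features import trial_feature_array

    x, ends = trial_feature_array(session, stats, grid, kind)
    labels = np.array(session.schedule.cue_types)
    return LabeledFeatureSet(
        x=x, window_ends_ms=ends, labels=labels,
        trial_ids=np.arange(len(labels)),
    )


@dataclass
class DecoderSpec:
    """RBF-SVM search space and fold structure."""

    gamma_grid: tuple = tuple(2.0 ** np.arange(-15, 4, 2))
    cost_grid: tuple = tuple(2.0 ** np.arange(-5, 16, 2))
    outer_folds: int = 10
    inner_folds: int = 5
    candidate_window_ends: tuple | None = None  # None -> TYPE_SEARCH_ENDS
    standardize: bool = True
    seed: int = 0

    def validate(self):
        if not len(self.gamma_grid) or not len(self.cost_grid):
            raise ValueError("hyperparameter grids must be non-empty")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")


def small_spec(seed: int = 0) -> DecoderSpec:
    """Reduced search space for quick runs.

    The gamma grid spans values matched to both the 84-dimensional
    single-window task and the 924-dimensional concatenated-epoch task
    (gamma of order 1/n_features for standardized inputs).
    """
    return DecoderSpec(
        gamma_grid=(2.0**-13, 2.0**-10, 2.0**-7, 2.0**-4, 2.0**-1),
        cost_grid=(2.0**0, 2.0**3, 2.0**6),
        outer_folds=5,
        inner_folds=3,
        seed=seed,
    )


@dataclass
class AccuracyCurve:
    """Outer-CV accuracy per window end plus the model-selected summary."""

    window_ends_ms: np.ndarray
    accuracy_percent: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    summary_accuracy: float
    summary_ci: tuple
    fold_choices: list = field(default_factory=list)

    def peak_window(self) -> float:
        return float(self.window_ends_ms[int(np.argmax(self.accuracy_percent))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_end_ms": self.window_ends_ms,
            "accuracy_percent": self.accuracy_percent,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


# --------------------------------------------------------------------------
# internals
# --------------------------------------------------------------------------

def _standardize(train, test):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _check_classes(y, context):
    if len(np.unique(y)) < 2:
        raise StratificationError(f"a class is absent in {context}")


def _fit_score(xtr, ytr, xte, yte, gamma, cost, standardize):
    if standardize:
        xtr, xte = _standardize(xtr, xte)
    clf = SVC(kernel="rbf", gamma=gamma, C=cost)
    clf.fit(xtr, ytr)
    return float(np.mean(clf.predict(xte) == yte))


def _inner_scores(x_windows, y, spec, rng_seed):
    """Mean inner-CV accuracy per (window, gamma, cost)."""
    n_w = x_windows.shape[1]
    scores = np.zeros((n_w, len(spec.gamma_grid), len(spec.cost_grid)))
    skf = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True,
                          random_state=rng_seed)
    for tr, te in skf.split(x_windows[:, 0, :], y):
        _check_classes(y[tr], "an inner training fold")
        for wi in range(n_w):
            for gi, gamma in enumerate(spec.gamma_grid):
                for ci, cost in enumerate(spec.cost_grid):
                    scores[wi, gi, ci] += _fit_score(
                        x_windows[tr][:, wi], y[tr],
                        x_windows[te][:, wi], y[te],
                        gamma, cost, spec.standardize)
    return scores / spec.inner_folds


def _select(scores, spec, windows):
    """Argmax with deterministic tie-breaks: cost, then gamma, then window."""
    best = None
    for ci, cost in enumerate(spec.cost_grid):
        for gi, gamma in enumerate(spec.gamma_grid):
            for wi in range(scores.shape[0]):
                s = scores[wi, gi, ci]
                if best is None or s > best[0] + 1e-12:
                    best = (s, wi, gi, ci)
    _, wi, gi, ci = best
    return wi, spec.gamma_grid[gi], spec.cost_grid[ci]


def _binom_ci(correct, total):
    lo, hi = proportion_confint(correct, total, alpha=0.05, method="beta")
    return 100.0 * lo, 100.0 * hi


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def nested_cv_type_accuracy(
    features: LabeledFeatureSet,
    spec: DecoderSpec | None = None,
    compute_curve: bool = True,
) -> AccuracyCurve:
    """Movement-type accuracy with nested window/hyperparameter selection.

    For each outer fold, inner CV over the training trials picks the
    (window, gamma, cost) triple with the highest inner accuracy; the outer
    test trials are then scored once with that choice.  The per-window curve
    re-uses the same inner scores, selecting hyperparameters per window.
    Chance level is 50%.
    """
    spec = spec or DecoderSpec()
    spec.validate()
    ends_all = features.window_ends_ms
    cand = spec.candidate_window_ends
    if cand is None:
        cand = [e for e in TYPE_SEARCH_ENDS
                if np.any(np.isclose(ends_all, e))]
        if not cand:
            cand = list(ends_all)
    w_idx = np.array([features.window_index(e) for e in cand])
    x = features.x[:, w_idx, :]
    y = np.asarray(features.labels)
    _check_classes(y, "the feature set")

    skf = StratifiedKFold(n_splits=spec.outer_folds, shuffle=True,
                          random_state=spec.seed)
    n_w = len(cand)
    correct_sum = 0
    total = 0
    win_correct = np.zeros(n_w)
    win_total = np.zeros(n_w)
    fold_choices = []
    for f, (tr, te) in enumerate(skf.split(x[:, 0, :], y)):
        _check_classes(y[tr], f"outer training fold {f}")
        _check_classes(y[te], f"outer test fold {f}")
        scores = _inner_scores(x[tr], y[tr], spec, spec.seed + 1000 + f)
        wi, gamma, cost = _select(scores, spec, cand)
        acc = _fit_score(x[tr][:, wi], y[tr], x[te][:, wi], y[te],
                         gamma, cost, spec.standardize)
        correct_sum += acc * len(te)
        total += len(te)
        fold_choices.append({
            "fold": f, "window_end_ms": float(cand[wi]),
            "gamma": float(gamma), "cost": float(cost),
            "test_accuracy": 100.0 * acc,
        })
        if compute_curve:
            for wj in range(n_w):
                sub = scores[wj:wj + 1]
                _, g_w, c_w = _select(sub, spec, [cand[wj]])
                a = _fit_score(x[tr][:, wj], y[tr], x[te][:, wj], y[te],
                               g_w, c_w, spec.standardize)
                win_correct[wj] += a * len(te)
                win_total[wj] += len(te)

    summary = 100.0 * correct_sum / total
    s_lo, s_hi = _binom_ci(int(round(correct_sum)), total)
    if compute_curve:
        accs = 100.0 * win_correct / win_total
        ci = np.array([_binom_ci(int(round(c)), int(t))
                       for c, t in zip(win_correct, win_total)])
        lo, hi = ci[:, 0], ci[:, 1]
    else:
        accs = np.full(n_w, np.nan)
        lo = hi = np.full(n_w, np.nan)
    return AccuracyCurve(
        window_ends_ms=np.asarray(cand, dtype=float),
        accuracy_percent=accs, ci_low=lo, ci_high=hi,
        summary_accuracy=summary, summary_ci=(s_lo, s_hi),
        fold_choices=fold_choices,
    )


def intention_examples(features: LabeledFeatureSet):
    """Concatenated 11-window examples for rest vs intention, two per trial.

    Returns (X, y, groups): y is 0 for rest, 1 for intention; groups carry
    the trial id so folds never split a trial across train and test.
    """
    rest = [features.window_index(e) for e in REST_EPOCH_ENDS]
    intent = [features.window_index(e) for e in INTENTION_EPOCH_ENDS]
    if set(rest) & set(intent):
        raise WindowBoundsError("rest and intention epochs overlap")
    n = features.x.shape[0]
    xr = features.x[:, rest, :].reshape(n, -1)
    xi = features.x[:, intent, :].reshape(n, -1)
    x = np.concatenate([xr, xi], axis=0)
    y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    groups = np.concatenate([features.trial_ids, features.trial_ids])
    return x, y, groups


def nested_cv_intention_accuracy(
    features: LabeledFeatureSet,
    spec: DecoderSpec | None = None,
) -> float:
    """Rest-vs-intention accuracy (%) with nested hyperparameter selection.

    Each trial contributes one rest and one intention example (11 windows
    concatenated each); folds are over trials, so both examples of a trial
    land on the same side of every split.  Chance level is 50%.
    """
    spec = spec or DecoderSpec()
    spec.validate()
    x, y, groups = intention_examples(features)
    trials = np.unique(groups)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(trials))
    folds = np.array_split(order, spec.outer_folds)

    correct = 0
    total = 0
    for f, fold_trials in enumerate(folds):
        te_trials = set(trials[fold_trials])
        te = np.array([i for i, g in enumerate(groups) if g in te_trials])
        tr = np.array([i for i, g in enumerate(groups) if g not in te_trials])
        _check_classes(y[tr], f"outer training fold {f}")
        inner = np.zeros((1, len(spec.gamma_grid), len(spec.cost_grid)))
        in_trials = np.array(sorted(set(groups[tr])))
        in_order = np.random.default_rng(spec.seed + 2000 + f).permutation(
            len(in_trials))
        in_folds = np.array_split(in_order, spec.inner_folds)
        for in_fold in in_folds:
            ite_trials = set(in_trials[in_fold])
            ite = np.array([i for i in tr if groups[i] in ite_trials])
            itr = np.array([i for i in tr if groups[i] not in ite_trials])
            for gi, gamma in enumerate(spec.gamma_grid):
                for ci, cost in enumerate(spec.cost_grid):
                    inner[0, gi, ci] += _fit_score(
                        x[itr], y[itr], x[ite], y[ite],
                        gamma, cost, spec.standardize)
        inner /= spec.inner_folds
        _, gamma, cost = _select(inner, spec, [0])
        acc = _fit_score(x[tr], y[tr], x[te], y[te], gamma, cost,
                         spec.standardize)
        correct += acc * len(te)
        total += len(te)
    return 100.0 * correct / total


def compare_feature_accuracies(
    table,
    paired_columns: tuple = (0, 1),
) -> dict:
    """Group comparison of decoding accuracy across feature kinds.

    ``table`` is subjects x feature-kinds (DataFrame or array).  Returns the
    one-way ANOVA across kinds (observations = subjects), Tukey-Kramer
    adjusted pairwise p-values, and a paired two-tailed t-test between the
    two designated columns.
    """
    df = pd.DataFrame(table)
    if df.shape[0] < 2:
        raise IncompleteTableError("need >= 2 subjects")
    if df.isna().any().any():
        raise IncompleteTableError("accuracy table has missing cells")
    k = df.shape[1]
    n = df.size
    groups = [df.iloc[:, j].to_numpy(float) for j in range(k)]
    if all(np.allclose(g, groups[0]) for g in groups):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = spstats.f_oneway(*groups)
    long_vals = np.concatenate(groups)
    long_grp = np.concatenate([[str(c)] * df.shape[0] for c in df.columns])
    tukey = pairwise_tukeyhsd(long_vals, long_grp, alpha=0.05)
    tukey_frame = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0])
    a, b = paired_columns
    t_stat, t_p = spstats.ttest_rel(df.iloc[:, a], df.iloc[:, b])
    return {
        "F": float(f_stat),
        "df": (k - 1, n - k),
        "p": float(p),
        "tukey": tukey_frame,
        "paired_t": float(t_stat),
        "paired_t_p": float(t_p),
    }


def shuffled_feature_set(features: LabeledFeatureSet, seed: int
                         ) -> LabeledFeatureSet:
    """Seeded label permutation for building the chance-level null."""
    rng = np.random.default_rng(seed)
    return features.with_labels(rng.permutation(features.labels))
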