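"""One-vs-rest task decoding from subregion-averaged trial activity.

The decoding stage works on four features per trial — the mean beta of
each IPL subregion (L-ant, L-post, R-ant, R-post) — and asks whether the
task a trial came from can be predicted in held-out subjects.  The
pipeline is, per leave-one-subject-out fold: class balancing by per-run
subsampling, confound removal (session number, session time, run time,
subject identity), run-wise standardization, then three one-vs-rest
logistic discriminants; the predicted task is the argmax of the decision
values.  Fold-averaged weights form the predictive signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .synthetic import SUBREGIONS, TASKS, TARGET_CONDITION, confounds_from_table

logger = logging.getLogger(__name__)

CHANCE_LEVEL = 100.0 / len(TASKS)
_META = ["trial_id", "subject", "session", "run", "task", "condition", "correct", "onset"]
_NUMERIC_CONFOUNDS = ["session", "session_time", "run_time"]


@dataclass(frozen=True)
class Signature:
    """Fold-averaged one-vs-rest weights: per task, 4 subregion weights
    plus an intercept (dimensionless after standardization)."""

    weights: pd.DataFrame  # index = task, columns = SUBREGIONS
    intercepts: pd.Series
    fold_weights: np.ndarray | None = None  # (n_folds, n_tasks, 4)
    fold_intercepts: np.ndarray | None = None  # (n_folds, n_tasks)


@dataclass(frozen=True)
class CVReport:
    overall_accuracy: float
    per_task_accuracy: dict[str, float]
    confusion: pd.DataFrame  # rows = true task, cols = predicted task
    chance_level: float = CHANCE_LEVEL
    n_test_trials: int = 0


def aggregate_subregions(betas: dict, parcs: dict, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-trial mean beta over the stable voxels of each named subregion.

    ``betas`` maps hemisphere -> TrialBetaMatrix and ``parcs`` maps
    hemisphere -> named Parcellation.  Control-condition, catch, and
    incorrect trials are dropped: only correct target-condition trials
    remain.  Returns trial metadata plus the four subregion columns.
    """
    hemis = {"left": "L", "right": "R"}
    ref = betas["left"].table if table is None else table
    out = ref.copy().reset_index(drop=True)
    for hemi, prefix in hemis.items():
        bm, parc = betas[hemi], parcs[hemi]
        if not parc.names:
            raise ValueError(f"{hemi} parcellation is unnamed; run name_subregions first")
        name_of = {code: nm for code, nm in parc.names.items()}
        for code, nm in name_of.items():
            sel = parc.stable & (parc.labels == code)
            if not sel.any():
                raise ValueError(f"subregion {nm!r} ({hemi}) has no stable voxels")
            col = f"{prefix}-{'ant' if nm == 'anterior' else 'post'}"
            out[col] = bm.data[:, sel].mean(axis=1)
    targets = set(TARGET_CONDITION.values())
    keep = out["condition"].isin(targets) & (out["correct"] == True)  # noqa: E712
    return out.loc[keep].reset_index(drop=True)


def balance_trials(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Within each (subject, session, run), subsample every task without
    replacement to that run's minimum per-task trial count.

    A run in which some task has no surviving (correct) trials contributes
    nothing and is dropped with a log record; a task absent from the
    design of a run altogether is an error.
    """
    rng = np.random.default_rng(seed)
    present = table.groupby("subject")["task"].unique()
    for subject, tasks in present.items():
        missing = sorted(set(TASKS) - set(tasks))
        if missing:
            raise ValueError(f"subject {subject!r} is missing task(s) {missing} entirely")
    pieces = []
    for (subject, session, run), grp in table.groupby(["subject", "session", "run"], sort=True):
        counts = grp["task"].value_counts()
        m = int(min(counts.reindex(list(TASKS), fill_value=0)))
        if m == 0:
            logger.info(
                "dropping subject=%s session=%s run=%s: a task has no correct trials",
                subject, session, run,
            )
            continue
        for task in TASKS:
            rows = grp.index[grp["task"] == task].to_numpy()
            pieces.append(rng.choice(rows, size=m, replace=False))
    if not pieces:
        raise ValueError("balancing removed every trial")
    idx = np.sort(np.concatenate(pieces))
    return table.loc[idx].reset_index(drop=True)


def deconfound(
    train: pd.DataFrame,
    test: pd.DataFrame | None = None,
    confound_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, list[str]]:
    """Remove confound-explained variation from the subregion columns.

    Subject identity is handled by within-subject mean-centering using each
    subject's own rows (train and test separately — no cross-subject
    leakage).  The numeric confounds (session number, session time, run
    time) are then regressed out by least squares fitted on training rows
    only and applied to test rows.  Zero-variance confound columns are
    dropped and reported in the returned list.
    """
    cols = confound_columns or _NUMERIC_CONFOUNDS
    feats = list(SUBREGIONS)

    def center_by_subject(df):
        out = df.copy()
        out[feats] = df[feats] - df.groupby("subject")[feats].transform("mean")
        return out

    def conf_matrix(df):
        if set(cols) <= set(df.columns):
            base = df[cols]
        else:
            base = confounds_from_table(df)[cols]
        return base.to_numpy(float)

    train = center_by_subject(train)
    test = center_by_subject(test) if test is not None else None
    C = conf_matrix(train)
    keep, dropped = [], []
    for j, name in enumerate(cols):
        if np.std(C[:, j]) > 0:
            keep.append(j)
        else:
            dropped.append(name)
            logger.info("deconfound: dropping zero-variance confound %r", name)
    C = C[:, keep]
    Cd = np.c_[np.ones(len(C)), C - C.mean(axis=0)] if C.shape[1] else np.ones((len(train), 1))
    Y = train[feats].to_numpy(float)
    B, *_ = np.linalg.lstsq(Cd, Y, rcond=None)
    train = train.copy()
    train[feats] = Y - Cd @ B
    if test is not None:
        Ct = conf_matrix(test)[:, keep]
        Ctd = np.c_[np.ones(len(Ct)), Ct - C.mean(axis=0)] if C.shape[1] else np.ones((len(test), 1))
        test = test.copy()
        test[feats] = test[feats].to_numpy(float) - Ctd @ B
    return train, test, dropped


def standardize_runwise(table: pd.DataFrame) -> pd.DataFrame:
    """Per (subject, session, run) and per subregion column: de-mean to
    zero and scale to unit variance (population convention, so a run with
    values (1, 3) maps to (-1, 1)).  A zero-variance column within a run
    is set to 0 and logged."""
    out = table.copy()
    feats = list(SUBREGIONS)
    for key, grp in table.groupby(["subject", "session", "run"], sort=False):
        vals = grp[feats].to_numpy(float)
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0)
        zero = sd == 0
        if zero.any():
            logger.info("standardize_runwise: zero-variance column(s) %s in run %s set to 0",
                        [feats[i] for i in np.flatnonzero(zero)], key)
        sd[zero] = 1.0
        z = (vals - mu) / sd
        z[:, zero] = 0.0
        out.loc[grp.index, feats] = z
    return out


def _fit_fold(train: pd.DataFrame, seed, C: float = 1.0):
    """Balance, deconfound, standardize training rows and fit three
    one-vs-rest logistic discriminants.  Returns (models, fit artifacts)."""
    train = balance_trials(train, seed=seed)
    train, _, _ = deconfound(train)
    train = standardize_runwise(train)
    X = train[list(SUBREGIONS)].to_numpy(float)
    y = train["task"].to_numpy()
    models = {}
    for task in TASKS:
        # default penalty is ridge (L2); strength controlled via C
        clf = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X, (y == task).astype(int))
        for w in wlist:
            if issubclass(w.category, ConvergenceWarning):
                logger.warning("fold fit for task %s did not converge: %s", task, w.message)
        models[task] = clf
    return models, train


def _prepare_test(train_raw: pd.DataFrame, test_raw: pd.DataFrame, seed) -> pd.DataFrame:
    test = balance_trials(test_raw, seed=seed)
    _, test, _ = deconfound(train_raw, test)
    return standardize_runwise(test)


def loso_crossvalidate(
    table: pd.DataFrame, seed: int = 0, C: float = 1.0
) -> tuple[CVReport, Signature]:
    """Leave-one-subject-out cross-validation of the task decoder.

    One fold per subject; within each fold the training subjects are
    balanced, deconfounded, and standardized, three one-vs-rest logistic
    models are fitted, and the held-out subject's (equally preprocessed)
    trials are predicted by the maximal decision value (ties broken by the
    fixed task order attention < semantics < social).
    """
    subjects = sorted(pd.unique(table["subject"]))
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 subjects")
    y_true, y_pred = [], []
    weights, intercepts = [], []
    for i, held in enumerate(subjects):
        fold_seed = np.random.SeedSequence([int(seed), i])
        s_train, s_test = fold_seed.spawn(2)
        train_raw = table[table["subject"] != held].reset_index(drop=True)
        test_raw = table[table["subject"] == held].reset_index(drop=True)
        models, _ = _fit_fold(train_raw, s_train, C=C)
        # deconfounding of test rows reuses the numeric-confound fit from the
        # *balanced* training rows, so rebuild it on the balanced set
        train_bal = balance_trials(train_raw, seed=s_train)
        test = balance_trials(test_raw, seed=s_test)
        _, test, _ = deconfound(train_bal, test)
        test = standardize_runwise(test)
        Xt = test[list(SUBREGIONS)].to_numpy(float)
        dec = np.column_stack([models[t].decision_function(Xt) for t in TASKS])
        ties = (dec == dec.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            logger.info("fold %s: %d tied decision(s) broken by task order", held, int(ties.sum()))
        pred = np.array(TASKS)[dec.argmax(axis=1)]
        y_true.append(test["task"].to_numpy())
        y_pred.append(pred)
        weights.append(np.stack([models[t].coef_[0] for t in TASKS]))
        intercepts.append(np.array([models[t].intercept_[0] for t in TASKS]))
    y_true = np.concatenate(y_true)
    y_pred = np.concatenate(y_pred)
    conf = pd.DataFrame(0, index=list(TASKS), columns=list(TASKS), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    overall = 100.0 * (y_true == y_pred).mean()
    per_task = {
        t: (100.0 * conf.loc[t, t] / conf.loc[t].sum()) if conf.loc[t].sum() else np.nan
        for t in TASKS
    }
    W = np.mean(weights, axis=0)
    b = np.mean(intercepts, axis=0)
    signature = Signature(
        weights=pd.DataFrame(W, index=list(TASKS), columns=list(SUBREGIONS)),
        intercepts=pd.Series(b, index=list(TASKS)),
        fold_weights=np.stack(weights),
        fold_intercepts=np.stack(intercepts),
    )
    report = CVReport(
        overall_accuracy=float(overall),
        per_task_accuracy={k: float(v) for k, v in per_task.items()},
        confusion=conf,
        n_test_trials=int(len(y_true)),
    )
    return report, signature
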