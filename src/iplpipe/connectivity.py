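"""Task-dependent functional-connectivity shifts (beta-series coupling).

For each task's correct target-condition trials, the coupling between
each IPL subregion and each cortical parcel is the Pearson correlation of
their trial-wise beta series (Fisher-z transformed for testing).  Whether
a coupling is task-*specific* is judged against a pooled permutation
baseline: task labels are shuffled across trials within subject
(preserving per-task counts) and the statistic — a task's z minus the
mean z over all three tasks — is recomputed, yielding an empirical null
of "indistinguishable connectivity across tasks".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic import SUBREGIONS, TASKS, TARGET_CONDITION

logger = logging.getLogger(__name__)

_Z_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivityTensor:
    """subregion x parcel x task coupling values.

    ``r`` holds Pearson correlations (nan where undefined), ``z`` their
    Fisher transforms (r clipped to +-(1 - 1e-7) to keep z finite).
    ``p`` and ``flags`` are filled by :func:`significant_shifts`.
    """

    r: np.ndarray
    z: np.ndarray
    subregions: tuple[str, ...]
    tasks: tuple[str, ...]
    n_trials: dict[str, int]
    p: np.ndarray | None = None
    flags: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.subregions):
            for j in range(self.r.shape[1]):
                for t, task in enumerate(self.tasks):
                    rows.append(
                        {
                            "subregion": s,
                            "parcel_id": j,
                            "task": task,
                            "r": self.r[i, j, t],
                            "z": self.z[i, j, t],
                            "p": self.p[i, j, t] if self.p is not None else np.nan,
                            "significant": bool(self.flags[i, j, t]) if self.flags is not None else False,
                        }
                    )
        return pd.DataFrame(rows)


def _select_target_trials(table: pd.DataFrame) -> np.ndarray:
    targets = set(TARGET_CONDITION.values())
    keep = table["condition"].isin(targets) & (table["correct"] == True)  # noqa: E712
    return keep.to_numpy()


def _corr_block(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations between A (n x a) and B (n x b)."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = A.std(axis=0)
    sb = B.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A.T @ B) / len(A) / np.outer(sa, sb)
    r[:, sb == 0] = np.nan
    r[sa == 0, :] = np.nan
    return r


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))


def taskwise_correlation(
    subregion_series: np.ndarray | pd.DataFrame,
    parcel_series: np.ndarray,
    table: pd.DataFrame,
    min_trials: int = 5,
) -> ConnectivityTensor:
    """Pearson r (and Fisher z) per (subregion, parcel, task).

    All three inputs are row-aligned over the same trials; only correct
    target-condition trials enter the correlations.  Cells whose series
    are constant come out as nan (flagged missing downstream).
    """
    if isinstance(subregion_series, pd.DataFrame):
        subregion_series = subregion_series[list(SUBREGIONS)].to_numpy(float)
    subregion_series = np.asarray(subregion_series, float)
    parcel_series = np.asarray(parcel_series, float)
    if not (len(subregion_series) == len(parcel_series) == len(table)):
        raise ValueError("subregion series, parcel series and trial table must be row-aligned")
    keep = _select_target_trials(table)
    sub = subregion_series[keep]
    par = parcel_series[keep]
    tasks_kept = table.loc[keep, "task"].to_numpy()
    n_sub, n_par = sub.shape[1], par.shape[1]
    r = np.full((n_sub, n_par, len(TASKS)), np.nan)
    n_trials = {}
    for t, task in enumerate(TASKS):
        rows = tasks_kept == task
        n_trials[task] = int(rows.sum())
        if n_trials[task] < min_trials:
            raise ValueError(
                f"task {task!r} has only {n_trials[task]} usable trials (< {min_trials})"
            )
        r[:, :, t] = _corr_block(sub[rows], par[rows])
    return ConnectivityTensor(
        r=r, z=_fisher_z(r), subregions=tuple(SUBREGIONS), tasks=tuple(TASKS), n_trials=n_trials
    )


@dataclass(frozen=True)
class PermutationNull:
    """Pooled-baseline null distributions per (subregion, parcel, task)."""

    null: np.ndarray  # (n_perm, n_sub, n_parcel, n_task)
    observed: np.ndarray  # (n_sub, n_parcel, n_task)
    n_perm: int
    strategy: str


def _shift_statistic(z: np.ndarray) -> np.ndarray:
    """Task-specific coupling shift: z(task) minus the across-task mean."""
    return z - z.mean(axis=2, keepdims=True)


def permutation_baseline(
    subregion_series: np.ndarray | pd.DataFrame,
    parcel_series: np.ndarray,
    table: pd.DataFrame,
    n_perm: int = 5000,
    seed: int = 0,
    strategy: str = "within_subject",
) -> PermutationNull:
    """Pooled permutation baseline across the three task conditions.

    Under each permutation the task labels of the usable trials are
    shuffled — within subject by default (``strategy="within_subject"``),
    or across the whole pool (``"pooled"``) — preserving per-task counts,
    and the shift statistic is recomputed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if strategy not in ("within_subject", "pooled"):
        raise ValueError(f"unknown permutation strategy {strategy!r}")
    if isinstance(subregion_series, pd.DataFrame):
        subregion_series = subregion_series[list(SUBREGIONS)].to_numpy(float)
    subregion_series = np.asarray(subregion_series, float)
    parcel_series = np.asarray(parcel_series, float)
    keep = _select_target_trials(table)
    sub = subregion_series[keep]
    par = parcel_series[keep]
    tasks_kept = table.loc[keep, "task"].to_numpy()
    subjects_kept = table.loc[keep, "subject"].to_numpy()
    if len(np.unique(tasks_kept)) < 2:
        raise ValueError("permutation baseline needs more than one task")
    rng = np.random.default_rng(seed)

    def z_for(labels: np.ndarray) -> np.ndarray:
        z = np.empty((sub.shape[1], par.shape[1], len(TASKS)))
        for t, task in enumerate(TASKS):
            rows = labels == task
            z[:, :, t] = _fisher_z(_corr_block(sub[rows], par[rows]))
        return z

    observed = _shift_statistic(z_for(tasks_kept))
    null = np.empty((n_perm, *observed.shape), dtype=np.float32)
    groups = (
        [np.flatnonzero(subjects_kept == s) for s in pd.unique(subjects_kept)]
        if strategy == "within_subject"
        else [np.arange(len(tasks_kept))]
    )
    labels = tasks_kept.copy()
    for p in range(n_perm):
        for g in groups:
            labels[g] = tasks_kept[g][rng.permutation(len(g))]
        null[p] = _shift_statistic(z_for(labels))
    return PermutationNull(null=null, observed=observed, n_perm=n_perm, strategy=strategy)


def significant_shifts(
    tensor: ConnectivityTensor,
    null: PermutationNull,
    alpha: float = 0.05,
    correction: str = "none",
) -> ConnectivityTensor:
    """Two-tailed empirical p-values with add-one correction.

    p = (1 + #{|null| >= |obs|}) / (1 + n_perm); a cell is flagged iff
    p < alpha.  The default applies no multiple-comparison correction
    across cells (the per-cell p < alpha reading); ``correction="bh"``
    flags by the Benjamini-Hochberg procedure at false-discovery rate
    ``alpha`` instead.
    """
    if null.null.shape[1:] != tensor.z.shape:
        raise ValueError("null distributions do not match the tensor's shape")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    obs = _shift_statistic(tensor.z)
    exceed = (np.abs(null.null) >= np.abs(obs)[None]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + null.n_perm)
    missing = ~np.isfinite(obs)
    p = np.where(missing, np.nan, p)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        flat_ok = np.isfinite(p.ravel())
        flags = np.zeros(p.size, dtype=bool)
        if flat_ok.any():
            flags[flat_ok] = multipletests(p.ravel()[flat_ok], alpha=alpha, method="fdr_bh")[0]
        flags = flags.reshape(p.shape)
    else:
        flags = np.where(missing, False, p < alpha)
    return replace(tensor, p=p, flags=flags)


def network_aggregate(
    tensor: ConnectivityTensor, lookup: pd.DataFrame, significant_only: bool = False
) -> pd.DataFrame:
    """Mean Fisher z per (subregion, network, task).

    ``lookup`` maps every parcel_id to one of the seven canonical networks;
    an unmapped parcel is an error.  With ``significant_only`` the mean is
    taken over flagged cells only (nan where a network has none).
    """
    n_parcels = tensor.z.shape[1]
    mapping = lookup.set_index("parcel_id")["network"]
    missing = sorted(set(range(n_parcels)) - set(mapping.index))
    if missing:
        raise ValueError(f"parcels without a network assignment: {missing[:10]}")
    networks = mapping.reindex(range(n_parcels)).to_numpy()
    if significant_only and tensor.flags is None:
        raise ValueError("tensor has no significance flags; run significant_shifts first")
    rows = []
    for i, sub in enumerate(tensor.subregions):
        for net in pd.unique(networks):
            cols = np.flatnonzero(networks == net)
            for t, task in enumerate(tensor.tasks):
                z = tensor.z[i, cols, t]
                if significant_only:
                    z = z[tensor.flags[i, cols, t]]
                rows.append(
                    {
                        "subregion": sub,
                        "network": net,
                        "task": task,
                        "mean_z": float(np.nanmean(z)) if z.size else np.nan,
                        "n_parcels": int(z.size),
                    }
                )
    return pd.DataFrame(rows)
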