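"""Second-level permutation test on directed modulation parameters.

Operates on subject-wise 4x4 task-modulation matrices (the "B-matrix"
parameters of a dynamic causal model, estimated upstream or synthesized).
For each task and directed connection, the statistic is the group mean of
(parameter under the task minus the mean of the same parameter under the
other two tasks).  The null — no parameter difference between tasks — is
built by permuting the three task assignments independently within each
subject (default) or by random sign flips of the subject-wise contrasts;
a connection is flagged when its absolute observed statistic exceeds the
configured percentile of its absolute null, with the empirical p-value
reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ModulationSet, SUBREGIONS, TASKS

logger = logging.getLogger(__name__)


def _contrast(values: np.ndarray) -> np.ndarray:
    """Per-subject task contrast: M[t] - mean of the other tasks.

    For T tasks this equals T/(T-1) * (M[t] - across-task mean).
    values: (..., n_tasks, 4, 4) -> same shape.
    """
    T = values.shape[-3]
    mean_all = values.mean(axis=-3, keepdims=True)
    return (values - mean_all) * (T / (T - 1))


def task_contrast_statistic(mods: ModulationSet, task: str) -> np.ndarray:
    """Group-mean 4x4 contrast statistic for one task."""
    if task not in mods.tasks:
        raise ValueError(f"task {task!r} not present in the modulation set")
    if len(mods.subjects) < 2:
        raise ValueError("at least 2 subjects required")
    t = mods.tasks.index(task)
    return _contrast(mods.values).mean(axis=0)[t]


@dataclass(frozen=True)
class ECTestResult:
    """Per (task, connection) permutation-test outcome."""

    table: pd.DataFrame  # task, source, target, statistic, strength, threshold, p, significant
    n_perm: int
    percentile: float
    strategy: str

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)


def permutation_test(
    mods: ModulationSet,
    n_perm: int = 10000,
    percentile: float = 99.9,
    seed: int = 0,
    include_self: bool = False,
    strategy: str = "label_perm",
) -> ECTestResult:
    """Random-effects permutation test for task-specific modulations.

    Flags a connection iff |observed statistic| > the ``percentile``-th
    percentile of its |null|; the add-one empirical p-value
    (1 + #{|null| >= |obs|}) / (1 + n_perm) is reported so either decision
    rule can be applied.  Self-connections are excluded by default.
    """
    S, T = len(mods.subjects), len(mods.tasks)
    if S < 2:
        raise ValueError("at least 2 subjects required")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    min_n = math.ceil(100.0 / (100.0 - percentile) - 1e-9)
    if n_perm < min_n:
        raise ValueError(
            f"n_perm={n_perm} too small for the {percentile} percentile; need at least {min_n}"
        )
    if strategy not in ("label_perm", "sign_flip"):
        raise ValueError(f"unknown permutation strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    values = mods.values  # (S, T, 4, 4)
    observed = _contrast(values).mean(axis=0)  # (T, 4, 4)
    if strategy == "label_perm":
        # independent permutation of the task assignments per subject
        orders = np.stack(
            [np.stack([rng.permutation(T) for _ in range(S)]) for _ in range(n_perm)]
        )  # (n_perm, S, T)
        permuted = values[np.arange(S)[None, :, None], orders]  # (n_perm, S, T, 4, 4)
        null = _contrast(permuted).mean(axis=1)  # (n_perm, T, 4, 4)
    else:
        contrasts = _contrast(values)  # (S, T, 4, 4)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
        null = np.einsum("ps,stij->ptij", signs, contrasts) / S
    thr = np.percentile(np.abs(null), percentile, axis=0)  # (T, 4, 4)
    exceed = (np.abs(null) >= np.abs(observed)[None]).sum(axis=0)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    strength = values.mean(axis=0)  # (T, 4, 4) group mean per task
    rows = []
    for t, task in enumerate(mods.tasks):
        for a, src in enumerate(mods.regions):
            for b, tgt in enumerate(mods.regions):
                if a == b and not include_self:
                    continue
                rows.append(
                    {
                        "task": task,
                        "source": src,
                        "target": tgt,
                        "statistic": observed[t, a, b],
                        "strength": strength[t, a, b],
                        "threshold": thr[t, a, b],
                        "p": pvals[t, a, b],
                        "significant": bool(abs(observed[t, a, b]) > thr[t, a, b]),
                    }
                )
    table = pd.DataFrame(rows)
    return ECTestResult(table=table, n_perm=n_perm, percentile=percentile, strategy=strategy)
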