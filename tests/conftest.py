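import numpy as np
import pandas as pd
import pytest

from iplpipe import synthetic as syn


def make_trial_table(n_subjects=3, n_per_task=10, target_only=True, seed=None):
    """Minimal hand-built trial table: correct target-condition trials only
    (optionally), one session/run, deterministic layout."""
    rows = []
    tid = 0
    for s in range(n_subjects):
        subject = f"sub-{s + 1:02d}"
        for task in syn.TASKS:
            conds = (
                [syn.TARGET_CONDITION[task]] * n_per_task
                if target_only
                else [syn.TARGET_CONDITION[task]] * n_per_task + [syn.CONTROL_CONDITION[task]] * n_per_task
            )
            for cond in conds:
                rows.append((tid, subject, 1, 1, task, cond, True, float(tid)))
                tid += 1
    df = pd.DataFrame(rows, columns=syn.TRIAL_COLUMNS)
    df["correct"] = df["correct"].astype("boolean")
    return df


@pytest.fixture(scope="session")
def small_design():
    return syn.generate_full_design(n_runs=4, n_subjects=4, seed=11)


@pytest.fixture(scope="session")
def small_rois():
    return syn.generate_roi((6, 8, 6), anterior_fraction=0.5, mirrored=True)


@pytest.fixture(scope="session")
def small_betas(small_design, small_rois):
    return syn.generate_both_hemispheres(
        small_design, small_rois, syn.EffectSpec.default(), seed=21
    )
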