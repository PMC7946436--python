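"""Synthetic trial-level data with planted ground truth.

This module emulates the outputs of a three-task event-related fMRI
experiment at the level the downstream analyses consume: trial tables,
trial-wise beta estimates inside left/right inferior-parietal-lobe (IPL)
region-of-interest grids, parcel-level beta series with task-dependent
coupling, and subject-wise directed modulation matrices.  Everything is
generated with explicit planted structure so that each analysis stage can
be validated against known truth without any external data.

The per-run trial design mirrors the experiment: 40 attentional
reorienting trials (8 invalid / 30 valid / 2 catch), 40 lexical-decision
trials (20 word / 20 pseudoword), and 6 perspective-taking trials
(3 false-belief / 3 true-belief) per run, with three sessions of four
runs each per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TASKS: tuple[str, ...] = ("attention", "semantics", "social")

#: per-run condition counts for each task
TASK_DESIGN: dict[str, dict[str, int]] = {
    "attention": {"invalid": 8, "valid": 30, "catch": 2},
    "semantics": {"word": 20, "pseudoword": 20},
    "social": {"false_belief": 3, "true_belief": 3},
}

#: condition isolating the cognitive process of interest, per task
TARGET_CONDITION: dict[str, str] = {
    "attention": "invalid",
    "semantics": "word",
    "social": "false_belief",
}

#: matched control condition, per task
CONTROL_CONDITION: dict[str, str] = {
    "attention": "valid",
    "semantics": "pseudoword",
    "social": "true_belief",
}

HEMISPHERES: tuple[str, str] = ("left", "right")
SUBREGION_NAMES: tuple[str, str] = ("anterior", "posterior")
#: canonical subregion column order used throughout the pipeline
SUBREGIONS: tuple[str, ...] = ("L-ant", "L-post", "R-ant", "R-post")

RUNS_PER_SESSION = 4
TRIAL_COLUMNS = ("trial_id", "subject", "session", "run", "task", "condition", "correct", "onset")

#: stimulus-on durations (s) per task, used only for onset bookkeeping
_TRIAL_DURATION = {"attention": 1.0, "semantics": 1.0, "social": 6.0}


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_design(
    task: str,
    n_runs: int = 12,
    n_subjects: int = 22,
    seed: int = 0,
    accuracy: float = 0.95,
    mean_iti: float = 3.8,
    sd_iti: float = 1.7,
    min_iti: float = 2.0,
) -> pd.DataFrame:
    """Generate the trial table for one task.

    Per run, condition counts follow the fixed experimental design
    (:data:`TASK_DESIGN`); trial order within a run is pseudo-randomized.
    Sessions group four consecutive runs.  Correctness is Bernoulli with
    probability ``accuracy`` for response trials and undefined (``pd.NA``)
    for catch trials.  Onsets are jittered inter-trial sequences; they are
    carried for completeness and unused downstream.
    """
    if task not in TASK_DESIGN:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASK_DESIGN)}")
    if n_runs < 1 or n_subjects < 1:
        raise ValueError("n_runs and n_subjects must be >= 1")
    rng = _rng(seed)
    rows = []
    trial_id = 0
    duration = _TRIAL_DURATION[task]
    for s in range(n_subjects):
        subject = f"sub-{s + 1:02d}"
        for r in range(n_runs):
            session = r // RUNS_PER_SESSION + 1
            run = r % RUNS_PER_SESSION + 1
            conditions = [c for c, n in TASK_DESIGN[task].items() for _ in range(n)]
            order = rng.permutation(len(conditions))
            onset = 10.0  # instruction screen
            for idx in order:
                cond = conditions[idx]
                if cond == "catch":
                    correct = pd.NA
                else:
                    correct = bool(rng.random() < accuracy)
                rows.append((trial_id, subject, session, run, task, cond, correct, round(onset, 3)))
                onset += duration + max(min_iti, rng.normal(mean_iti, sd_iti))
                trial_id += 1
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["correct"] = df["correct"].astype("boolean")
    return df


def generate_full_design(
    n_runs: int = 12, n_subjects: int = 22, seed: int = 0, accuracy: float = 0.95
) -> pd.DataFrame:
    """All three tasks' trial tables combined, re-numbered consecutively.

    Each run contains all three task blocks (task order fixed here; the
    analyses are order-agnostic).
    """
    children = np.random.SeedSequence(seed).spawn(len(TASKS))
    parts = [
        generate_design(t, n_runs=n_runs, n_subjects=n_subjects, seed=ss, accuracy=accuracy)
        for t, ss in zip(TASKS, children)
    ]
    df = pd.concat(parts, ignore_index=True)
    df = df.sort_values(["subject", "session", "run", "task", "trial_id"], kind="stable")
    df = df.reset_index(drop=True)
    df["trial_id"] = np.arange(len(df))
    return df


# ---------------------------------------------------------------------------
# ROI grids


@dataclass(frozen=True)
class ROIMask:
    """A rectangular voxel grid standing in for one hemisphere's IPL ROI.

    ``coords`` are integer grid coordinates (n_voxels x 3); ``affine`` maps
    grid to millimetre reference space (RAS: +x right, +y anterior).
    """

    coords: np.ndarray
    shape: tuple[int, int, int]
    affine: np.ndarray
    hemisphere: str

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def volume(self, values: np.ndarray, background=0) -> np.ndarray:
        """Scatter per-voxel ``values`` into a dense 3-D array."""
        vol = np.full(self.shape, background, dtype=np.asarray(values).dtype)
        vol[self.coords[:, 0], self.coords[:, 1], self.coords[:, 2]] = values
        return vol

    def mm_coords(self) -> np.ndarray:
        homog = np.c_[self.coords, np.ones(self.n_voxels)]
        return (homog @ self.affine.T)[:, :3]


def _hemisphere_affine(hemisphere: str, voxel_size: float = 2.0) -> np.ndarray:
    """Grid->mm affine; the two hemispheres are mirror images across x=0.

    Left-hemisphere grid index i maps to negative x so that flipping the
    first grid axis realizes the left-right mirror used by the congruency
    analysis.  The second grid axis ascends toward anterior (+y).
    """
    aff = np.eye(4)
    aff[1, 1] = voxel_size
    aff[2, 2] = voxel_size
    aff[1, 3] = -60.0
    aff[2, 3] = 10.0
    if hemisphere == "left":
        aff[0, 0] = -voxel_size
        aff[0, 3] = -4.0
    else:
        aff[0, 0] = voxel_size
        aff[0, 3] = 4.0
    return aff


def generate_roi(
    shape: tuple[int, int, int] = (10, 11, 10),
    anterior_fraction: float = 0.5,
    mirrored: bool = True,
    seed: int = 0,
) -> tuple[ROIMask, ROIMask, dict[str, np.ndarray]]:
    """Create left/right ROI grids with planted anterior/posterior labels.

    The planted boundary is a plane perpendicular to the second grid axis
    (the anterior axis), placed at ``(1 - anterior_fraction) * ny`` in
    continuous voxel units; a voxel (center j + 0.5) is anterior iff its
    center lies anterior of the plane.  With ``mirrored`` the right
    hemisphere's label volume is the left-right flip of the left one;
    otherwise it is computed independently by the same rule (identical for
    these box-shaped grids, but kept distinct for irregular masks).

    Returns ``(left_mask, right_mask, labels)`` where ``labels`` maps
    hemisphere to a per-voxel array with 1 = anterior, 2 = posterior.
    """
    if any(int(s) <= 0 for s in shape):
        raise ValueError(f"degenerate grid shape {shape}")
    if not 0.0 < anterior_fraction < 1.0:
        raise ValueError("anterior_fraction must be in (0, 1)")
    shape = tuple(int(s) for s in shape)
    del seed  # grids are deterministic; seed kept for interface stability
    grid = np.indices(shape).reshape(3, -1).T
    ny = shape[1]
    plane = (1.0 - anterior_fraction) * ny

    def plant(coords: np.ndarray) -> np.ndarray:
        anterior = (coords[:, 1] + 0.5) > plane
        return np.where(anterior, 1, 2).astype(np.int8)

    left = ROIMask(grid.copy(), shape, _hemisphere_affine("left"), "left")
    right = ROIMask(grid.copy(), shape, _hemisphere_affine("right"), "right")
    left_labels = plant(left.coords)
    if mirrored:
        flipped = np.flip(left.volume(left_labels), axis=0)
        right_labels = flipped[right.coords[:, 0], right.coords[:, 1], right.coords[:, 2]]
    else:
        right_labels = plant(right.coords)
    labels = {"left": left_labels, "right": np.asarray(right_labels, dtype=np.int8)}
    return left, right, labels


# ---------------------------------------------------------------------------
# Trial-wise voxel activity


@dataclass(frozen=True)
class EffectSpec:
    """Planted activity structure for the voxel-level generator.

    ``effects`` maps (task, condition) to a mapping from
    (hemisphere, subregion-name) to a mean activity shift in beta units;
    every (task, condition) pair occurring in a design must be present
    (an empty inner mapping means "no effect anywhere").  ``boundary_taper``
    (voxel units) smoothly blends the anterior/posterior effects across the
    planted boundary, producing genuinely ambiguous border voxels.
    """

    effects: Mapping[tuple[str, str], Mapping[tuple[str, str], float]]
    noise_sd: float = 1.0
    subject_sd: float = 0.5
    baseline: float = 0.0
    boundary_taper: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise_sd and subject_sd must be >= 0")

    @classmethod
    def default(cls, effect: float = 1.0, **kwargs) -> "EffectSpec":
        """The planted specialization pattern used throughout the package.

        Attentional reorienting drives the right anterior subregion,
        semantic (lexical) decisions the left anterior subregion, and
        social cognition (perspective taking) both posterior subregions.
        Control conditions carry no effect.
        """
        effects: dict[tuple[str, str], dict[tuple[str, str], float]] = {
            (t, c): {} for t in TASKS for c in TASK_DESIGN[t]
        }
        effects[("attention", "invalid")] = {("right", "anterior"): effect}
        effects[("semantics", "word")] = {("left", "anterior"): effect}
        effects[("social", "false_belief")] = {
            ("left", "posterior"): effect,
            ("right", "posterior"): effect,
        }
        return cls(effects=effects, **kwargs)

    @classmethod
    def null(cls, **kwargs) -> "EffectSpec":
        """Zero planted effects everywhere (global-null generator)."""
        return cls(effects={(t, c): {} for t in TASKS for c in TASK_DESIGN[t]}, **kwargs)


@dataclass(frozen=True)
class TrialBetaMatrix:
    """Trial-wise activity estimates (trials x voxels, beta units)."""

    data: np.ndarray
    table: pd.DataFrame
    mask: ROIMask
    planted_labels: np.ndarray | None = None

    def __post_init__(self):
        if self.data.shape[0] != len(self.table):
            raise ValueError("row count must equal trial-table length")
        if self.data.shape[1] != self.mask.n_voxels:
            raise ValueError("column count must equal mask size")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("beta values must be finite")


def _effect_field(
    mask: ROIMask, labels: np.ndarray, spec: EffectSpec, task: str, condition: str
) -> np.ndarray:
    """Per-voxel mean shift for one (task, condition), with boundary blend."""
    entry = spec.effects[(task, condition)]
    hemi = mask.hemisphere
    ant = float(entry.get((hemi, "anterior"), 0.0))
    post = float(entry.get((hemi, "posterior"), 0.0))
    if spec.boundary_taper <= 0:
        return np.where(labels == 1, ant, post)
    # signed distance of voxel centers from the planted boundary plane,
    # reconstructed from the labels along the anterior axis
    y = mask.coords[:, 1] + 0.5
    if (labels == 1).any() and (labels == 2).any():
        plane = 0.5 * (y[labels == 1].min() + y[labels == 2].max())
    else:
        plane = y.min() - 1.0
    w = 1.0 / (1.0 + np.exp(-(y - plane) / spec.boundary_taper))  # 1 on anterior side
    return w * ant + (1.0 - w) * post


def generate_trial_betas(
    design: pd.DataFrame,
    mask: ROIMask,
    labels: np.ndarray,
    spec: EffectSpec,
    seed: int = 0,
) -> TrialBetaMatrix:
    """Simulate trial-wise beta estimates for one hemisphere.

    value = baseline + subject offset + planted effect(task, condition,
    hemisphere, subregion) + i.i.d. Gaussian noise.
    """
    pairs = set(zip(design["task"], design["condition"]))
    missing = sorted(p for p in pairs if p not in spec.effects)
    if missing:
        raise ValueError(f"EffectSpec missing effect entry for (task, condition) pairs: {missing}")
    rng = _rng(seed)
    subjects = pd.unique(design["subject"])
    offsets = dict(zip(subjects, rng.normal(0.0, spec.subject_sd, len(subjects))))
    n_trials, n_vox = len(design), mask.n_voxels
    data = rng.normal(0.0, spec.noise_sd, size=(n_trials, n_vox))
    data += spec.baseline
    data += np.array([offsets[s] for s in design["subject"]])[:, None]
    fields = {
        (t, c): _effect_field(mask, labels, spec, t, c) for (t, c) in pairs
    }
    keys = list(zip(design["task"], design["condition"]))
    data += np.array([fields[k] for k in keys])
    return TrialBetaMatrix(data=data, table=design.reset_index(drop=True), mask=mask,
                           planted_labels=np.asarray(labels))


def generate_both_hemispheres(
    design: pd.DataFrame,
    rois: tuple[ROIMask, ROIMask, dict[str, np.ndarray]],
    spec: EffectSpec,
    seed: int = 0,
) -> dict[str, TrialBetaMatrix]:
    """Convenience: trial betas for left and right hemisphere grids."""
    left, right, labels = rois
    s_left, s_right = np.random.SeedSequence(seed).spawn(2)
    return {
        "left": generate_trial_betas(design, left, labels["left"], spec, seed=s_left),
        "right": generate_trial_betas(design, right, labels["right"], spec, seed=s_right),
    }


# ---------------------------------------------------------------------------
# Subregion-level features (pre-aggregated)

#: planted per-task subregion pattern mirroring EffectSpec.default()
DEFAULT_SUBREGION_EFFECTS: dict[tuple[str, str], float] = {
    ("attention", "R-ant"): 1.0,
    ("semantics", "L-ant"): 1.0,
    ("social", "L-post"): 1.0,
    ("social", "R-post"): 1.0,
}


def generate_subregion_features(
    design: pd.DataFrame,
    effects: Mapping[tuple[str, str], float] | None = DEFAULT_SUBREGION_EFFECTS,
    noise_sd: float = 1.0,
    subject_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulate the four subregion-averaged activity columns.

    Emulates the output of voxel aggregation without the voxel level:
    for correct target-condition trials, the trial's task adds
    ``effects[(task, subregion)]`` to that subregion's column; all columns
    additionally carry a per-subject offset and unit-level Gaussian noise.
    ``effects=None`` plants nothing (null data).

    Returns the trial metadata plus the columns L-ant, L-post, R-ant,
    R-post, restricted to correct target-condition trials (the form the
    classifier stage consumes).
    """
    effects = dict(effects or {})
    rng = _rng(seed)
    targets = set(TARGET_CONDITION.values())
    keep = design["condition"].isin(targets) & (design["correct"] == True)  # noqa: E712
    df = design.loc[keep].reset_index(drop=True).copy()
    subjects = pd.unique(design["subject"])
    offsets = dict(zip(subjects, rng.normal(0.0, subject_sd, len(subjects))))
    values = rng.normal(0.0, noise_sd, size=(len(df), len(SUBREGIONS)))
    values += np.array([offsets[s] for s in df["subject"]])[:, None]
    for j, sub in enumerate(SUBREGIONS):
        shift = df["task"].map(lambda t, sub=sub: effects.get((t, sub), 0.0)).to_numpy(float)
        values[:, j] += shift
    for j, sub in enumerate(SUBREGIONS):
        df[sub] = values[:, j]
    return df


# ---------------------------------------------------------------------------
# Parcel-level beta series

YEO7_NETWORKS: tuple[str, ...] = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")


def default_network_lookup(n_parcels: int = 400) -> pd.DataFrame:
    """Parcel -> network assignment in seven contiguous blocks."""
    blocks = np.array_split(np.arange(n_parcels), len(YEO7_NETWORKS))
    rows = [
        (int(p), net) for net, idx in zip(YEO7_NETWORKS, blocks) for p in idx
    ]
    return pd.DataFrame(rows, columns=["parcel_id", "network"])


@dataclass(frozen=True)
class CouplingSpec:
    """Planted subregion-parcel coupling.

    ``couplings`` is a sequence of (task, subregion-name, parcel indices,
    rho): on trials of ``task``, each listed parcel's value is
    rho * standardized subregion series + sqrt(1 - rho^2) * noise.
    Unlisted (task, parcel) combinations are pure noise.
    """

    couplings: Sequence[tuple[str, str, Sequence[int], float]] = ()
    n_parcels: int = 400
    lookup: pd.DataFrame = field(default_factory=lambda: default_network_lookup(400))

    def __post_init__(self):
        for task, sub, parcels, rho in self.couplings:
            if task not in TASKS:
                raise ValueError(f"unknown task {task!r}")
            if sub not in SUBREGIONS:
                raise ValueError(f"unknown subregion {sub!r}")
            if abs(rho) > 1:
                raise ValueError(f"|rho| must be <= 1, got {rho}")
            parcels = np.asarray(parcels)
            if parcels.size and (parcels.min() < 0 or parcels.max() >= self.n_parcels):
                raise ValueError(
                    f"parcel index out of range 0..{self.n_parcels - 1} in coupling for {task}/{sub}"
                )

    @classmethod
    def default(cls, n_parcels: int = 400, rho: float = 0.5) -> "CouplingSpec":
        """Plant couplings echoing the qualitative network profile:
        attention couples the right anterior subregion to dorsal-attention
        parcels, semantics the left anterior subregion to fronto-parietal
        parcels, social cognition the posterior subregions to default-mode
        parcels."""
        lookup = default_network_lookup(n_parcels)
        by_net = {n: lookup.loc[lookup["network"] == n, "parcel_id"].to_numpy() for n in YEO7_NETWORKS}
        take = lambda net, m=8: list(by_net[net][:m])
        couplings = [
            ("attention", "R-ant", take("DAN"), rho),
            ("semantics", "L-ant", take("FPN"), rho),
            ("social", "L-post", take("DMN"), rho),
            ("social", "R-post", take("DMN"), rho),
        ]
        return cls(couplings=couplings, n_parcels=n_parcels, lookup=lookup)


def generate_parcel_betas(
    design: pd.DataFrame,
    subregion_series: np.ndarray | pd.DataFrame,
    spec: CouplingSpec,
    seed: int = 0,
) -> np.ndarray:
    """Trial-wise beta series for ``spec.n_parcels`` cortical parcels.

    Row-aligned with ``design``.  Planted couplings act on all trials of
    their task; everything else is standard-normal noise.
    """
    if isinstance(subregion_series, pd.DataFrame):
        subregion_series = subregion_series[list(SUBREGIONS)].to_numpy(float)
    subregion_series = np.asarray(subregion_series, dtype=float)
    if subregion_series.shape != (len(design), len(SUBREGIONS)):
        raise ValueError("subregion_series must be trials x 4, aligned with design")
    rng = _rng(seed)
    out = rng.normal(size=(len(design), spec.n_parcels))
    task_arr = design["task"].to_numpy()
    for task, sub, parcels, rho in spec.couplings:
        rows = np.flatnonzero(task_arr == task)
        if rows.size < 2:
            continue
        s = subregion_series[rows, SUBREGIONS.index(sub)]
        sd = s.std()
        z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
        for p in np.asarray(parcels, dtype=int):
            out[rows, p] = rho * z + np.sqrt(1.0 - rho**2) * out[rows, p]
    return out


# ---------------------------------------------------------------------------
# Directed modulation matrices


@dataclass(frozen=True)
class ModulationTruth:
    """Ground-truth task-specific 4x4 directed modulation matrices."""

    matrices: Mapping[str, np.ndarray]
    subject_sd: float = 0.5

    def __post_init__(self):
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        for t, m in self.matrices.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (4, 4) or not np.all(np.isfinite(m)):
                raise ValueError(f"matrix for task {t!r} must be finite 4x4")

    @classmethod
    def null(cls, subject_sd: float = 0.5) -> "ModulationTruth":
        return cls(matrices={t: np.zeros((4, 4)) for t in TASKS}, subject_sd=subject_sd)

    @classmethod
    def default(cls, subject_sd: float = 0.5) -> "ModulationTruth":
        """A sparse task-dependent pattern: each task modulates a couple of
        directed links among the four subregions (signs echo the kind of
        facilitatory/inhibitory asymmetries the method is meant to detect)."""
        idx = {s: i for i, s in enumerate(SUBREGIONS)}
        mats = {t: np.zeros((4, 4)) for t in TASKS}
        mats["attention"][idx["R-post"], idx["R-ant"]] = -1.5
        mats["semantics"][idx["L-ant"], idx["R-ant"]] = 1.0
        mats["semantics"][idx["R-ant"], idx["L-post"]] = -2.0
        mats["social"][idx["L-post"], idx["L-ant"]] = 1.2
        mats["social"][idx["R-post"], idx["R-ant"]] = 2.0
        return cls(matrices=mats, subject_sd=subject_sd)


@dataclass(frozen=True)
class ModulationSet:
    """Subject x task x (4x4) modulatory parameter estimates."""

    values: np.ndarray  # (n_subjects, n_tasks, 4, 4)
    subjects: tuple[str, ...]
    tasks: tuple[str, ...] = TASKS
    regions: tuple[str, ...] = SUBREGIONS

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != (len(self.subjects), len(self.tasks), 4, 4):
            raise ValueError("values must be (n_subjects, n_tasks, 4, 4)")
        if not np.all(np.isfinite(v)):
            raise ValueError("modulation values must be finite")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for si, subj in enumerate(self.subjects):
            for ti, task in enumerate(self.tasks):
                for a, src in enumerate(self.regions):
                    for b, tgt in enumerate(self.regions):
                        rows.append((subj, task, src, tgt, self.values[si, ti, a, b]))
        return pd.DataFrame(rows, columns=["subject", "task", "source", "target", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ModulationSet":
        subjects = tuple(pd.unique(df["subject"]))
        tasks = tuple(pd.unique(df["task"]))
        regions = tuple(pd.unique(df["source"]))
        values = np.zeros((len(subjects), len(tasks), len(regions), len(regions)))
        s_idx = {s: i for i, s in enumerate(subjects)}
        t_idx = {t: i for i, t in enumerate(tasks)}
        r_idx = {r: i for i, r in enumerate(regions)}
        for row in df.itertuples(index=False):
            values[s_idx[row.subject], t_idx[row.task], r_idx[row.source], r_idx[row.target]] = row.value
        return cls(values=values, subjects=subjects, tasks=tasks, regions=regions)


def generate_modulations(
    truth: ModulationTruth, n_subjects: int = 22, seed: int = 0
) -> ModulationSet:
    """Subject-wise modulation matrices: truth + between-subject noise."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (the permutation test is undefined otherwise)")
    rng = _rng(seed)
    subjects = tuple(f"sub-{i + 1:02d}" for i in range(n_subjects))
    base = np.stack([np.asarray(truth.matrices[t], dtype=float) for t in TASKS])
    noise = rng.normal(0.0, truth.subject_sd, size=(n_subjects, len(TASKS), 4, 4))
    return ModulationSet(values=base[None] + noise, subjects=subjects)


def confounds_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Derive the numeric confound columns from trial metadata.

    run_time is the within-run onset; session_time adds the run offset
    within the session (runs are laid out back-to-back at a nominal run
    length); session is the session number.
    """
    nominal_run_length = 600.0
    run_time = table["onset"].to_numpy(float)
    session_time = run_time + (table["run"].to_numpy(float) - 1) * nominal_run_length
    return pd.DataFrame(
        {
            "session": table["session"].to_numpy(float),
            "session_time": session_time,
            "run_time": run_time,
            "subject": table["subject"].to_numpy(),
        },
        index=table.index,
    )
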