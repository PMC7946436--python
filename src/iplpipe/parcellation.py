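"""Consensus parcellation of an ROI into subregions.

Pipeline: voxel-wise feature construction from target-condition contrasts
(pooled across subjects), an ensemble of k-means runs with many random
centroid initializations, a majority vote over cluster-validity indices to
pick the number of clusters, consensus labeling with exclusion of voxels
whose assignment varies across initializations, anatomical naming along
the anterior-posterior axis, and a cross-hemisphere congruency analysis
after flipping the left-right axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linear_sum_assignment

from . import _validity
from .synthetic import ROIMask, TrialBetaMatrix, TARGET_CONDITION

logger = logging.getLogger(__name__)


class DegenerateFeaturesError(ValueError):
    """Raised when the feature matrix carries no variance to cluster."""


@dataclass(frozen=True)
class FeatureMatrix:
    """Voxels x features; features are (subject, task) contrast estimates."""

    values: np.ndarray
    feature_ids: tuple[tuple[str, str], ...]
    mask: ROIMask

    def __post_init__(self):
        if self.values.shape != (self.mask.n_voxels, len(self.feature_ids)):
            raise ValueError("values must be (n_voxels, n_features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")


def build_features(
    betas: TrialBetaMatrix,
    target_conditions: dict[str, str] | None = None,
    rest_baseline: float = 0.0,
) -> FeatureMatrix:
    """Per-voxel target-condition contrast features, pooled across subjects.

    For every (subject, task) the feature is the mean beta over that
    subject's *correct* target-condition trials, minus the rest baseline
    (zero in the synthetic setting).  Incorrect trials are excluded.
    """
    targets = dict(target_conditions or TARGET_CONDITION)
    table = betas.table
    subjects = list(pd.unique(table["subject"]))
    tasks = list(targets)
    cols = []
    ids = []
    for subject in subjects:
        for task in tasks:
            sel = (
                (table["subject"] == subject)
                & (table["task"] == task)
                & (table["condition"] == targets[task])
                & (table["correct"] == True)  # noqa: E712
            )
            if not sel.any():
                raise ValueError(
                    f"subject {subject!r} has zero correct {targets[task]!r} trials in task {task!r}"
                )
            cols.append(betas.data[sel.to_numpy()].mean(axis=0) - rest_baseline)
            ids.append((subject, task))
    values = np.column_stack(cols)
    return FeatureMatrix(values=values, feature_ids=tuple(ids), mask=betas.mask)


# ---------------------------------------------------------------------------
# k-means ensemble


@dataclass(frozen=True)
class PartitionEnsemble:
    """R partitions of the voxels for one k, with per-partition WCSS."""

    labels: np.ndarray  # (R, V), values in 0..k-1
    inertia: np.ndarray  # (R,)
    k: int

    @property
    def n_partitions(self) -> int:
        return self.labels.shape[0]

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.inertia))

    @property
    def best_labels(self) -> np.ndarray:
        return self.labels[self.best_index]


def kmeans_ensemble(
    features: FeatureMatrix | np.ndarray,
    k: int,
    n_init: int = 1000,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    chunk: int = 256,
) -> PartitionEnsemble:
    """Ensemble of k-means runs, one per random centroid initialization.

    Each run draws k distinct data points as initial centroids and iterates
    Lloyd updates (squared-Euclidean) until the maximal centroid movement
    falls below ``tol`` or ``max_iter`` is reached.  All runs are advanced
    simultaneously in vectorized chunks; an empty cluster keeps its
    previous centroid.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    V, F = X.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if k >= V:
        raise ValueError(f"k={k} must be smaller than the number of voxels ({V})")
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise DegenerateFeaturesError("feature matrix has zero variance; nothing to cluster")
    rng = np.random.default_rng(seed)
    x_sq = (X**2).sum(axis=1)
    all_labels = np.empty((n_init, V), dtype=np.int32)
    all_inertia = np.empty(n_init)
    for start in range(0, n_init, chunk):
        R = min(chunk, n_init - start)
        init_idx = np.stack([rng.choice(V, size=k, replace=False) for _ in range(R)])
        C = X[init_idx]  # (R, k, F)
        active = np.ones(R, dtype=bool)
        labels = np.zeros((R, V), dtype=np.int32)
        for _ in range(max_iter):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            Ca = C[idx]  # (r, k, F)
            # squared distances (V, r, k) via expansion
            cross = np.einsum("vf,rkf->vrk", X, Ca)
            d2 = x_sq[:, None, None] - 2.0 * cross + (Ca**2).sum(axis=2)[None]
            lab = d2.argmin(axis=2).T.astype(np.int32)  # (r, V)
            labels[idx] = lab
            # centroid update via sparse aggregation
            rows = (lab + k * np.arange(idx.size)[:, None]).ravel()
            cols = np.tile(np.arange(V), idx.size)
            A = sparse.csr_matrix(
                (np.ones(rows.size), (rows, cols)), shape=(idx.size * k, V)
            )
            sums = A @ X  # (r*k, F)
            counts = np.asarray(A.sum(axis=1)).ravel()
            newC = Ca.reshape(idx.size * k, F).copy()
            nz = counts > 0
            newC[nz] = sums[nz] / counts[nz, None]
            newC = newC.reshape(idx.size, k, F)
            shift = ((newC - Ca) ** 2).sum(axis=2).max(axis=1)
            C[idx] = newC
            active[idx[shift >= tol**2]] = True
            active[idx[shift < tol**2]] = False
        # final assignment + inertia against converged centroids
        cross = np.einsum("vf,rkf->vrk", X, C)
        d2 = x_sq[:, None, None] - 2.0 * cross + (C**2).sum(axis=2)[None]
        lab = d2.argmin(axis=2).T.astype(np.int32)
        inertia = np.take_along_axis(d2, lab.T[:, :, None], axis=2)[:, :, 0].sum(axis=0)
        all_labels[start : start + R] = lab
        all_inertia[start : start + R] = np.maximum(inertia, 0.0)
    return PartitionEnsemble(labels=all_labels, inertia=all_inertia, k=k)


# ---------------------------------------------------------------------------
# validity votes and k selection


@dataclass(frozen=True)
class VoteTable:
    """Per-index values over candidate k, each index's vote, abstentions."""

    values: pd.DataFrame  # index = index name, columns = candidate k
    votes: dict[str, int | None]
    k_range: tuple[int, int]

    @property
    def abstentions(self) -> list[str]:
        return [name for name, v in self.votes.items() if v is None]


def _wcss_of(X, labels):
    total = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        total += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(total)


def compute_validity_votes(
    features: FeatureMatrix | np.ndarray,
    ensembles: dict[int, PartitionEnsemble],
    k_range: tuple[int, int] = (2, 7),
) -> VoteTable:
    """Evaluate the index battery on each k's best partition and record votes.

    Scalar indices vote their own optimum (max or min) over the candidate
    range.  Hartigan and Krzanowski-Lai operate on within-cluster sums of
    squares over successive k; W at k_min-1 and k_max+1 are supplied by the
    analytic k=1 value and, when available, the extra ensemble at k_max+1.
    An index undefined on some partition abstains (logged).
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    kmin, kmax = k_range
    candidates = list(range(kmin, kmax + 1))
    missing = [k for k in candidates if k not in ensembles]
    if missing:
        raise ValueError(f"ensembles missing for candidate k values {missing}")
    best = {k: ensembles[k].best_labels for k in ensembles}
    D = _validity.pairwise_distances(X)
    values = pd.DataFrame(index=list(_validity.SCALAR_INDICES), columns=candidates, dtype=float)
    votes: dict[str, int | None] = {}
    for name, (fn, rule) in _validity.SCALAR_INDICES.items():
        row = {}
        for k in candidates:
            row[k] = fn(X, best[k], D)
        values.loc[name] = pd.Series(row)
        finite = {k: v for k, v in row.items() if np.isfinite(v)}
        if not finite:
            votes[name] = None
            logger.warning("validity index %s abstained (undefined on all candidates)", name)
            continue
        opt = max(finite.values()) if rule == "max" else min(finite.values())
        votes[name] = min(k for k, v in finite.items() if v == opt)

    # successive-k indices need W over an extended range
    wcss = {1: _wcss_of(X, np.zeros(len(X), dtype=int))}
    for k, ens in ensembles.items():
        wcss[k] = float(ens.inertia.min())
    krange = range(kmin, kmax + 1)
    h_vote, H = _validity.hartigan_votes(wcss, krange, n=len(X))
    votes["hartigan"] = h_vote
    values.loc["hartigan"] = pd.Series({k: H.get(k, np.nan) for k in candidates})
    kl_vote, KL = _validity.krzanowski_lai_votes(wcss, krange, p=X.shape[1])
    votes["krzanowski_lai"] = kl_vote
    values.loc["krzanowski_lai"] = pd.Series({k: KL.get(k, np.nan) for k in candidates})
    for name in ("hartigan", "krzanowski_lai"):
        if votes[name] is None:
            logger.warning("validity index %s abstained (insufficient WCSS range)", name)
    return VoteTable(values=values, votes=votes, k_range=k_range)


def select_k(votes: VoteTable) -> tuple[int, float]:
    """Majority vote: modal k among non-abstaining indices.

    Ties are broken toward smaller k.  Returns (k_star, agreement %) where
    agreement is the share of non-abstaining indices voting for k_star.
    """
    cast = [v for v in votes.votes.values() if v is not None]
    if not cast:
        raise ValueError("all validity indices abstained; cannot select k")
    counts = pd.Series(cast).value_counts()
    top = counts.max()
    k_star = int(min(k for k, c in counts.items() if c == top))
    agreement = 100.0 * top / len(cast)
    return k_star, float(agreement)


# ---------------------------------------------------------------------------
# consensus labeling


@dataclass(frozen=True)
class Parcellation:
    """Voxel-to-subregion assignment with stability flags and names.

    ``labels`` holds aligned consensus codes 1..k (modal aligned label);
    ``stable`` marks voxels whose aligned assignment was identical in at
    least the stability-threshold share of ensemble members.  Unstable
    voxels carry no subregion membership downstream.  ``names`` maps the
    code to an anatomical name once :func:`name_subregions` has run.
    """

    labels: np.ndarray
    stable: np.ndarray
    stability: np.ndarray
    k: int
    mask: ROIMask | None = None
    names: dict[int, str] = field(default_factory=dict)

    @property
    def n_stable(self) -> int:
        return int(self.stable.sum())

    def label_volume(self) -> np.ndarray:
        """Dense volume: 0 = background/unstable, codes 1..k elsewhere.

        If names are assigned, codes are remapped so 1 = anterior and
        2 = posterior (ordinal along the axis for k > 2)."""
        if self.mask is None:
            raise ValueError("parcellation has no mask attached")
        codes = np.where(self.stable, self.labels, 0)
        if self.names:
            order = {"anterior": 1, "posterior": 2}
            remap = np.zeros(self.k + 1, dtype=int)
            ordinal = sorted(self.names.items(), key=lambda kv: kv[1])
            for rank, (code, nm) in enumerate(ordinal, start=1):
                remap[code] = order.get(nm, rank)
            codes = remap[codes]
        return self.mask.volume(codes)


def _align_to_reference(labels: np.ndarray, ref: np.ndarray, k: int) -> np.ndarray:
    """Permute labels to maximize overlap with the reference partition
    (optimal one-to-one matching on the label confusion matrix)."""
    conf = np.zeros((k, k), dtype=np.int64)
    np.add.at(conf, (labels, ref), 1)
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.empty(k, dtype=np.int32)
    mapping[rows] = cols
    return mapping[labels]


def consensus_labels(
    ensemble: PartitionEnsemble,
    stability_threshold: float = 1.0,
    mask: ROIMask | None = None,
) -> Parcellation:
    """Merge an ensemble into one consensus parcellation.

    Every member is aligned to the reference member (lowest WCSS) by
    maximum-overlap one-to-one label matching; the consensus label is the
    modal aligned label, and a voxel is stable iff that modal label occurs
    in at least ``stability_threshold`` of the members.
    """
    if ensemble.n_partitions == 0:
        raise ValueError("empty ensemble")
    if not 0.0 < stability_threshold <= 1.0:
        raise ValueError("stability_threshold must be in (0, 1]")
    k = ensemble.k
    ref = ensemble.best_labels
    R, V = ensemble.labels.shape
    counts = np.zeros((V, k), dtype=np.int32)
    for r in range(R):
        aligned = _align_to_reference(ensemble.labels[r], ref, k)
        np.add.at(counts, (np.arange(V), aligned), 1)
    modal = counts.argmax(axis=1)
    stability = counts[np.arange(V), modal] / R
    stable = stability >= stability_threshold - 1e-12
    return Parcellation(
        labels=(modal + 1).astype(np.int32),
        stable=stable,
        stability=stability,
        k=k,
        mask=mask,
    )


def name_subregions(parc: Parcellation, mask: ROIMask | None = None) -> Parcellation:
    """Name clusters along the anterior-posterior axis.

    The cluster whose (stable-voxel) center of mass lies more anterior —
    larger +y in millimetre space via the mask affine, equivalently larger
    second-grid-axis coordinate — is "anterior"; the other "posterior".
    For k > 2 names are ordinal from posterior to anterior.
    """
    mask = mask or parc.mask
    if mask is None:
        raise ValueError("a mask is required for anatomical naming")
    mm = mask.mm_coords()
    coms = {}
    for code in range(1, parc.k + 1):
        sel = parc.stable & (parc.labels == code)
        if not sel.any():
            raise ValueError(f"cluster {code} has no stable voxels; cannot name")
        coms[code] = mm[sel, 1].mean()
    ordered = sorted(coms, key=lambda c: coms[c])  # posterior -> anterior
    vals = [coms[c] for c in ordered]
    if len(set(np.round(vals, 9))) < len(vals):
        raise ValueError("subregion centers of mass coincide on the anterior axis; naming degenerate")
    if parc.k == 2:
        names = {ordered[0]: "posterior", ordered[1]: "anterior"}
    else:
        names = {c: f"segment-{i + 1}" for i, c in enumerate(ordered)}
    return replace(parc, names=names, mask=mask)


def centers_of_mass(parc: Parcellation) -> pd.DataFrame:
    """Per-subregion volume and grid/mm centers of mass (stable voxels)."""
    mask = parc.mask
    if mask is None:
        raise ValueError("parcellation has no mask attached")
    mm = mask.mm_coords()
    rows = []
    for code in range(1, parc.k + 1):
        sel = parc.stable & (parc.labels == code)
        name = parc.names.get(code, str(code))
        rows.append(
            {
                "label": name,
                "n_voxels": int(sel.sum()),
                "com_grid_x": mask.coords[sel, 0].mean(),
                "com_grid_y": mask.coords[sel, 1].mean(),
                "com_grid_z": mask.coords[sel, 2].mean(),
                "com_mm_x": mm[sel, 0].mean(),
                "com_mm_y": mm[sel, 1].mean(),
                "com_mm_z": mm[sel, 2].mean(),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-hemisphere congruency


@dataclass(frozen=True)
class CongruencyReport:
    """Topographic overlap after flipping the left-right axis.

    ``overall`` gives, per hemisphere, the percentage of that hemisphere's
    ROI voxels also present in the other hemisphere's flipped mask.
    ``per_subregion`` gives, per named subregion (L-ant, L-post, R-ant,
    R-post), the percentage of shared stably-labeled voxels whose mirrored
    counterpart carries the same name; ``None`` when undefined (no shared
    voxels).
    """

    overall: dict[str, float]
    per_subregion: dict[str, float | None]
    n_shared: int
    overall_concordance: float | None = None


def hemispheric_congruency(left: Parcellation, right: Parcellation) -> CongruencyReport:
    """Quantify left/right topographic agreement after an x-axis flip."""
    if left.mask is None or right.mask is None:
        raise ValueError("both parcellations need masks")
    if left.mask.shape != right.mask.shape:
        raise ValueError(
            f"grid shapes differ: {left.mask.shape} vs {right.mask.shape}"
        )
    if not (left.names and right.names):
        raise ValueError("run name_subregions on both parcellations first")
    lvol = left.label_volume()
    rvol = np.flip(right.label_volume(), axis=0)
    lmask = left.mask.volume(np.ones(left.mask.n_voxels, dtype=np.int8)) > 0
    rmask_flipped = np.flip(
        right.mask.volume(np.ones(right.mask.n_voxels, dtype=np.int8)), axis=0
    ) > 0
    shared = lmask & rmask_flipped
    overall = {
        "left": 100.0 * shared.sum() / lmask.sum() if lmask.sum() else 0.0,
        "right": 100.0 * shared.sum() / rmask_flipped.sum() if rmask_flipped.sum() else 0.0,
    }
    per: dict[str, float | None] = {}
    labeled = shared & (lvol > 0) & (rvol > 0)
    for prefix, vol, other in (("L", lvol, rvol), ("R", rvol, lvol)):
        for code, short in ((1, "ant"), (2, "post")):
            sel = labeled & (vol == code)
            key = f"{prefix}-{short}"
            per[key] = (
                100.0 * (other[sel] == code).sum() / sel.sum() if sel.sum() else None
            )
    concordance = (
        100.0 * (lvol[labeled] == rvol[labeled]).sum() / labeled.sum() if labeled.sum() else None
    )
    return CongruencyReport(
        overall=overall, per_subregion=per, n_shared=int(shared.sum()),
        overall_concordance=concordance,
    )


# ---------------------------------------------------------------------------
# one-call driver


@dataclass(frozen=True)
class ParcellationResult:
    votes: VoteTable
    k_star: int
    agreement: float
    parcellation: Parcellation
    ensembles: dict[int, PartitionEnsemble]


def parcellate(
    features: FeatureMatrix,
    k_range: tuple[int, int] = (2, 7),
    n_init: int = 1000,
    stability_threshold: float = 1.0,
    seed: int = 0,
) -> ParcellationResult:
    """Full parcellation of one hemisphere: ensembles over the candidate
    range (plus k_max+1 for the successive-k indices), validity vote,
    consensus at the winning k, and anatomical naming."""
    kmin, kmax = k_range
    children = np.random.SeedSequence(seed).spawn(kmax + 2 - kmin)
    ensembles = {
        k: kmeans_ensemble(features, k, n_init=n_init, seed=ss)
        for k, ss in zip(range(kmin, kmax + 2), children)
    }
    votes = compute_validity_votes(features, ensembles, k_range=k_range)
    k_star, agreement = select_k(votes)
    parc = consensus_labels(ensembles[k_star], stability_threshold, mask=features.mask)
    parc = name_subregions(parc)
    return ParcellationResult(
        votes=votes, k_star=k_star, agreement=agreement, parcellation=parc,
        ensembles={k: ensembles[k] for k in range(kmin, kmax + 1)},
    )
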