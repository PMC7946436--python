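"""Consensus parcellation: features, ensemble, votes, consensus, naming."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from iplpipe import parcellation as par
from iplpipe import synthetic as syn
from iplpipe.parcellation import DegenerateFeaturesError

from conftest import make_trial_table


def _toy_mask(coords, hemisphere="left", shape=None, affine=None):
    coords = np.asarray(coords)
    shape = shape or tuple(coords.max(axis=0) + 1)
    affine = np.eye(4) if affine is None else affine
    return syn.ROIMask(coords=coords, shape=tuple(int(s) for s in shape),
                       affine=affine, hemisphere=hemisphere)


# ---------------------------------------------------------------------------
# build_features


def test_build_features_one_per_subject_task(small_betas):
    feats = par.build_features(small_betas["left"])
    assert feats.values.shape == (small_betas["left"].mask.n_voxels, 4 * 3)
    assert len(set(feats.feature_ids)) == 12


def test_build_features_hand_computed_toy():
    """4 voxels, 2 trials per condition with printed values: features equal
    hand-computed correct-target-trial means."""
    table = pd.DataFrame(
        {
            "trial_id": range(6),
            "subject": ["s1"] * 6,
            "session": [1] * 6,
            "run": [1] * 6,
            "task": ["attention"] * 4 + ["semantics"] * 2,
            "condition": ["invalid", "invalid", "valid", "valid", "word", "word"],
            "correct": [True, True, True, False, True, True],
            "onset": np.arange(6.0),
        }
    )
    table["correct"] = table["correct"].astype("boolean")
    data = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [3.0, 2.0, 1.0, 0.0],
            [9.0, 9.0, 9.0, 9.0],
            [7.0, 7.0, 7.0, 7.0],
            [2.0, 4.0, 6.0, 8.0],
            [4.0, 4.0, 4.0, 4.0],
        ]
    )
    mask = _toy_mask([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    betas = syn.TrialBetaMatrix(data=data, table=table, mask=mask)
    feats = par.build_features(
        betas, target_conditions={"attention": "invalid", "semantics": "word"}
    )
    # hand arithmetic: attention = mean of trials 0,1; semantics = mean of 4,5
    expected = np.column_stack([[2.0, 2.0, 2.0, 2.0], [3.0, 4.0, 5.0, 6.0]])
    assert np.allclose(feats.values, expected)


def test_build_features_rejects_subject_without_correct_targets():
    table = make_trial_table(n_subjects=1, n_per_task=3)
    table.loc[table["task"] == "social", "correct"] = False
    table["correct"] = table["correct"].astype("boolean")
    mask = _toy_mask([[0, 0, 0], [0, 1, 0]])
    betas = syn.TrialBetaMatrix(
        data=np.zeros((len(table), 2)), table=table, mask=mask
    )
    with pytest.raises(ValueError, match="sub-01.*social"):
        par.build_features(betas)


# ---------------------------------------------------------------------------
# kmeans ensemble


def test_kmeans_ensemble_separated_clouds_all_partitions_agree():
    rng = np.random.default_rng(0)
    X = np.r_[rng.normal(0, 0.5, (30, 3)), rng.normal(8, 0.5, (30, 3))]
    ens = par.kmeans_ensemble(X, k=2, n_init=25, seed=1)
    ref = ens.labels[0]
    for lab in ens.labels[1:]:
        assert adjusted_rand_score(ref, lab) == 1.0


def test_kmeans_ensemble_matches_sklearn_solution():
    """Independent cross-check: the ensemble's best partition agrees (up to
    label permutation) with scikit-learn's own k-means on the same data."""
    rng = np.random.default_rng(3)
    X = np.r_[rng.normal(0, 1, (40, 4)), rng.normal(6, 1, (40, 4))]
    ens = par.kmeans_ensemble(X, k=2, n_init=50, seed=2)
    sk = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
    assert adjusted_rand_score(ens.best_labels, sk.labels_) == 1.0
    assert ens.inertia.min() == pytest.approx(sk.inertia_, rel=1e-6)


def test_kmeans_ensemble_size_one_and_duplicates():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
    ens = par.kmeans_ensemble(X, k=2, n_init=1, seed=0)
    assert ens.n_partitions == 1
    lab = ens.labels[0]
    assert lab[0] == lab[1] and lab[2] == lab[3] == lab[4] and lab[0] != lab[2]


def test_kmeans_ensemble_rejects_k_not_less_than_voxels():
    X = np.random.default_rng(0).normal(size=(4, 2))
    with pytest.raises(ValueError, match="k=4"):
        par.kmeans_ensemble(X, k=4, n_init=1, seed=0)


def test_kmeans_ensemble_rejects_degenerate_features():
    X = np.ones((20, 3))
    with pytest.raises(DegenerateFeaturesError):
        par.kmeans_ensemble(X, k=2, n_init=1, seed=0)


def test_kmeans_ensemble_deterministic_under_seed():
    X = np.random.default_rng(5).normal(size=(50, 3))
    a = par.kmeans_ensemble(X, k=3, n_init=20, seed=9)
    b = par.kmeans_ensemble(X, k=3, n_init=20, seed=9)
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.inertia, b.inertia)


# ---------------------------------------------------------------------------
# validity votes and k selection


def test_calinski_harabasz_hand_computed_six_points():
    """Printed 6-point, 2-cluster toy: CH equals the hand-computed
    between/within variance ratio."""
    X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
    labels = np.array([0, 0, 0, 1, 1, 1])
    # hand arithmetic: centroids 1 and 11, grand mean 6
    # BGSS = 3*(1-6)^2 + 3*(11-6)^2 = 150; WGSS = (1+0+1)*2 = 4
    # CH = (150/(2-1)) / (4/(6-2)) = 150
    from iplpipe._validity import calinski_harabasz

    assert calinski_harabasz(X, labels) == pytest.approx(150.0, abs=1e-10)


def test_validity_votes_two_blobs_majority_two():
    rng = np.random.default_rng(1)
    X = np.r_[rng.normal(0, 1, (20, 2)), rng.normal(10, 1, (20, 2))]
    ens = {k: par.kmeans_ensemble(X, k, n_init=50, seed=k) for k in range(2, 9)}
    votes = par.compute_validity_votes(X, ens, (2, 7))
    # the max/min-rule indices with a clear optimum all agree on 2
    for name in (
        "calinski_harabasz", "silhouette", "davies_bouldin", "dunn", "c_index",
        "point_biserial", "pbm", "ratkowsky_lance", "xie_beni", "krzanowski_lai",
    ):
        assert votes.votes[name] == 2, name
    k_star, agreement = par.select_k(votes)
    assert k_star == 2
    assert agreement >= 75.0


def test_validity_votes_match_independent_recomputation():
    """Index values equal brute-force recomputation from first principles
    (pairwise-distance definitions) on a small random fixture."""
    rng = np.random.default_rng(4)
    X = np.r_[rng.normal(0, 1, (8, 2)), rng.normal(4, 1, (8, 2))]
    labels = np.array([0] * 8 + [1] * 8)
    from iplpipe import _validity as v

    D = v.pairwise_distances(X)
    # brute-force within/between distance lists
    dw, db = [], []
    for i in range(16):
        for j in range(i + 1, 16):
            (dw if labels[i] == labels[j] else db).append(np.linalg.norm(X[i] - X[j]))
    dw, db = np.array(dw), np.array(db)
    assert v.mcclain_rao(X, labels, D) == pytest.approx(dw.mean() / db.mean(), abs=1e-10)
    alld = np.sort(np.concatenate([dw, db]))
    cind = (dw.sum() - alld[: len(dw)].sum()) / (alld[-len(dw):].sum() - alld[: len(dw)].sum())
    assert v.c_index(X, labels, D) == pytest.approx(cind, abs=1e-10)
    pb = (db.mean() - dw.mean()) * np.sqrt(len(dw) * len(db)) / (len(dw) + len(db)) / alld.std()
    assert v.point_biserial(X, labels, D) == pytest.approx(pb, abs=1e-10)
    dunn = db.min() / max(
        dw[: len(dw)].max(),
        dw.max(),
    )
    assert v.dunn(X, labels, D) == pytest.approx(dunn, abs=1e-10)


def test_select_k_examples():
    def mk(votes_list):
        votes = {f"idx{i}": v for i, v in enumerate(votes_list)}
        values = pd.DataFrame(index=list(votes), columns=[2, 3, 4], dtype=float)
        return par.VoteTable(values=values, votes=votes, k_range=(2, 4))

    assert par.select_k(mk([2] * 24 + [3])) == (2, pytest.approx(96.0))
    # tie broken toward smaller k
    assert par.select_k(mk([2] * 12 + [3] * 12)) == (2, pytest.approx(50.0))
    k, agree = par.select_k(mk([4] * 7 + [2] * 6 + [3] * 6))
    assert k == 4 and agree == pytest.approx(100 * 7 / 19)


def test_select_k_all_abstain_rejected():
    vt = par.VoteTable(
        values=pd.DataFrame(), votes={"a": None, "b": None}, k_range=(2, 7)
    )
    with pytest.raises(ValueError, match="abstain"):
        par.select_k(vt)


# ---------------------------------------------------------------------------
# consensus labels


def test_consensus_single_partition_all_stable():
    ens = par.PartitionEnsemble(
        labels=np.array([[0, 0, 1, 1]]), inertia=np.array([1.0]), k=2
    )
    parc = par.consensus_labels(ens)
    assert parc.stable.all()
    assert parc.n_stable == 4


def test_consensus_invariant_to_global_label_swap():
    base = np.array([0, 0, 1, 1, 0])
    ens = par.PartitionEnsemble(
        labels=np.stack([base, 1 - base]), inertia=np.array([1.0, 2.0]), k=2
    )
    parc = par.consensus_labels(ens)
    assert parc.stable.all()
    assert len(set(parc.labels[base == 0])) == 1


def test_consensus_single_flipped_voxel_unstable():
    """10 partitions, one voxel flipped in exactly one: only that voxel is
    unstable at threshold 1.0 (agreement counted by brute force)."""
    base = np.array([0, 0, 0, 1, 1, 1])
    labels = np.tile(base, (10, 1))
    labels[3, 2] = 1  # flip voxel 2 in partition 3
    ens = par.PartitionEnsemble(labels=labels, inertia=np.ones(10), k=2)
    parc = par.consensus_labels(ens, stability_threshold=1.0)
    assert list(~parc.stable) == [False, False, True, False, False, False]
    # brute-force agreement count for the flipped voxel
    assert parc.stability[2] == pytest.approx(9 / 10)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_consensus_invariant_under_member_relabeling(seed):
    """Relabeling any ensemble member leaves the consensus unchanged."""
    rng = np.random.default_rng(seed)
    # noisy copies of one base partition: the maximum-overlap matching is
    # unique, so the invariance is well-posed
    base = np.repeat([0, 1, 2], 8).astype(np.int32)
    labels = np.tile(base, (6, 1))
    noise = rng.random(labels.shape) < 0.1
    labels[noise] = rng.integers(0, 3, size=int(noise.sum()))
    labels[:, :3] = [0, 1, 2]
    inertia = rng.random(6)
    ens = par.PartitionEnsemble(labels=labels, inertia=inertia, k=3)
    parc = par.consensus_labels(ens, stability_threshold=0.5)
    relabeled = labels.copy()
    m = int(rng.integers(0, 6))
    perm = rng.permutation(3)
    relabeled[m] = perm[labels[m]]
    parc2 = par.consensus_labels(
        par.PartitionEnsemble(labels=relabeled, inertia=inertia, k=3),
        stability_threshold=0.5,
    )
    assert np.array_equal(parc.stable, parc2.stable)
    assert np.array_equal(parc.stability, parc2.stability)


def test_consensus_threshold_monotonicity():
    rng = np.random.default_rng(8)
    labels = rng.integers(0, 2, size=(20, 30)).astype(np.int32)
    ens = par.PartitionEnsemble(labels=labels, inertia=rng.random(20), k=2)
    stable_sets = []
    for thr in (0.5, 0.7, 0.9, 1.0):
        stable_sets.append(par.consensus_labels(ens, thr).stable)
    for lo, hi in zip(stable_sets, stable_sets[1:]):
        assert set(np.flatnonzero(hi)) <= set(np.flatnonzero(lo))


def test_consensus_empty_ensemble_rejected():
    ens = par.PartitionEnsemble(
        labels=np.empty((0, 5), dtype=np.int32), inertia=np.empty(0), k=2
    )
    with pytest.raises(ValueError, match="empty"):
        par.consensus_labels(ens)


# ---------------------------------------------------------------------------
# naming and congruency


def _planted_parcellation(hemisphere="left", shape=(4, 6, 2), frac=0.5):
    left, right, labels = syn.generate_roi(shape, frac, mirrored=True)
    mask = left if hemisphere == "left" else right
    lab = labels[hemisphere]
    parc = par.Parcellation(
        labels=lab.astype(np.int32),
        stable=np.ones(mask.n_voxels, dtype=bool),
        stability=np.ones(mask.n_voxels),
        k=2,
        mask=mask,
    )
    return par.name_subregions(parc)


def test_name_subregions_matches_planted_truth():
    parc = _planted_parcellation()
    # planted code 1 is anterior by construction
    assert parc.names[1] == "anterior" and parc.names[2] == "posterior"


def test_name_subregions_by_mm_centers():
    """Clusters at mm y = -32 vs y = -61: the y=-32 cluster is anterior."""
    affine = np.eye(4)
    affine[1, 3] = -70.0  # grid y=9 -> mm y=-61; grid y=38 -> mm y=-32
    coords = np.array([[0, 9, 0], [1, 9, 0], [0, 38, 0], [1, 38, 0]])
    mask = syn.ROIMask(coords=coords, shape=(2, 40, 1), affine=affine, hemisphere="left")
    parc = par.Parcellation(
        labels=np.array([1, 1, 2, 2], dtype=np.int32),
        stable=np.ones(4, bool), stability=np.ones(4), k=2, mask=mask,
    )
    named = par.name_subregions(parc)
    assert named.names[2] == "anterior"  # the y = -32 cluster
    coms = par.centers_of_mass(named)
    assert coms.set_index("label").loc["anterior", "com_mm_y"] == pytest.approx(-32.0)


def test_name_subregions_equal_centers_rejected():
    mask = _toy_mask([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
    parc = par.Parcellation(
        labels=np.array([1, 2, 1, 2], dtype=np.int32),
        stable=np.ones(4, bool), stability=np.ones(4), k=2, mask=mask,
    )
    with pytest.raises(ValueError, match="degenerate"):
        par.name_subregions(parc)


def test_congruency_identical_mirrored_is_100():
    left = _planted_parcellation("left")
    right = _planted_parcellation("right")
    rep = par.hemispheric_congruency(left, right)
    assert rep.overall == {"left": 100.0, "right": 100.0}
    assert all(v == 100.0 for v in rep.per_subregion.values())


def test_congruency_disjoint_masks_zero_and_undefined():
    affine_l = syn._hemisphere_affine("left")
    affine_r = syn._hemisphere_affine("right")
    shape = (4, 4, 1)
    coords_l = np.array([[0, y, 0] for y in range(4)])
    coords_r = np.array([[1, y, 0] for y in range(4)])  # flip -> x=2, disjoint
    def mk(coords, affine, hemi):
        mask = syn.ROIMask(coords=coords, shape=shape, affine=affine, hemisphere=hemi)
        parc = par.Parcellation(
            labels=np.array([2, 2, 1, 1], dtype=np.int32),
            stable=np.ones(4, bool), stability=np.ones(4), k=2, mask=mask,
        )
        return par.name_subregions(parc)
    rep = par.hemispheric_congruency(mk(coords_l, affine_l, "left"), mk(coords_r, affine_r, "right"))
    assert rep.overall == {"left": 0.0, "right": 0.0}
    assert all(v is None for v in rep.per_subregion.values())


def test_congruency_hand_counted_fixture():
    """20-voxel hemispheres sharing 15 voxels after the flip, 3 of them
    discordant: overall 75.0% per hemisphere, concordance 80.0% (hand
    count: 12 of 15 shared voxels carry the same name)."""
    shape = (5, 4, 2)
    # left: the full 5x4 sheet at z=0 (20 voxels); anterior label for y >= 2
    coords_l = np.array([[x, y, 0] for x in range(5) for y in range(4)])
    labels_l = np.where(coords_l[:, 1] >= 2, 1, 2).astype(np.int32)
    # right: the 15 z=0 voxels with y >= 1 (each maps into the left sheet
    # after the x-flip) plus 5 voxels at z=1 that can never be shared
    coords_r = np.array(
        [[x, y, 0] for x in range(5) for y in range(1, 4)]
        + [[x, 0, 1] for x in range(5)]
    )
    labels_r = np.where(coords_r[:, 1] >= 2, 1, 2).astype(np.int32)
    # three discordant voxels: flip the label of three y=3 right voxels
    flip = (coords_r[:, 1] == 3) & (coords_r[:, 0] <= 2)
    assert flip.sum() == 3
    labels_r[flip] = 2

    def mk(coords, labels, hemi):
        mask = syn.ROIMask(coords=coords, shape=shape, affine=np.eye(4), hemisphere=hemi)
        parc = par.Parcellation(
            labels=labels, stable=np.ones(len(coords), bool),
            stability=np.ones(len(coords)), k=2, mask=mask,
        )
        return par.name_subregions(parc)

    rep = par.hemispheric_congruency(mk(coords_l, labels_l, "left"), mk(coords_r, labels_r, "right"))
    assert rep.n_shared == 15
    assert rep.overall["left"] == pytest.approx(75.0)
    assert rep.overall["right"] == pytest.approx(75.0)
    assert rep.overall_concordance == pytest.approx(80.0)
    # hand-counted per-subregion breakdown
    assert rep.per_subregion["L-ant"] == pytest.approx(70.0)
    assert rep.per_subregion["L-post"] == pytest.approx(100.0)
    assert rep.per_subregion["R-ant"] == pytest.approx(100.0)
    assert rep.per_subregion["R-post"] == pytest.approx(100 * 5 / 8)


def test_recovery_of_planted_subregions(small_betas, small_rois):
    """End-to-end: the vote picks the planted two-cluster structure and the
    consensus labels recover the planted anterior/posterior split."""
    feats = par.build_features(small_betas["left"])
    res = par.parcellate(feats, n_init=100, seed=3)
    assert res.k_star == 2
    truth = small_rois[2]["left"]
    parc = res.parcellation
    ari = adjusted_rand_score(truth[parc.stable], parc.labels[parc.stable])
    assert ari >= 0.9
    assert parc.names[1] in ("anterior", "posterior")


def test_unstable_voxels_sit_near_planted_boundary():
    """With graded boundary noise (tapered effects), voxels that lose
    stability lie closer to the planted boundary than stable ones."""
    design = syn.generate_full_design(n_runs=2, n_subjects=3, seed=4)
    rois = syn.generate_roi((5, 10, 5), 0.5)
    spec = syn.EffectSpec.default(
        effect=1.5, noise_sd=1.5, subject_sd=0.0, boundary_taper=2.0
    )
    betas = syn.generate_trial_betas(design, rois[0], rois[2]["left"], spec, seed=5)
    feats = par.build_features(betas)
    ens = par.kmeans_ensemble(feats, k=2, n_init=100, seed=6)
    parc = par.consensus_labels(ens, stability_threshold=1.0, mask=rois[0])
    if 0 < parc.n_stable < rois[0].n_voxels:
        dist = np.abs(rois[0].coords[:, 1] + 0.5 - 5.0)  # distance to plane
        assert dist[~parc.stable].mean() < dist[parc.stable].mean()
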