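import numpy as np
import pytest

from psyctrl import (
    GeneratorConfig,
    SnapshotSet,
    assemble_snapshots,
    build_self_constructed,
    dmdc_fit,
    generate_cohort,
    generate_full_rank_trajectory,
    input_vector,
    predict_cohort,
    predict_post,
)
from psyctrl.models import ModelError
from psyctrl.study_data import StudyData


def _study_with_network(net, n=3):
    return StudyData(
        participants=["P01"],
        items=[f"item{k}" for k in range(n)],
        baseline=np.full((1, n), 3),
        post=np.full((1, n, n), 3),
        direction=np.ones((1, n), dtype=int),
        drawn_networks={"P01": net},
    )


def test_self_constructed_single_edge_convention():
    # drawn edge source item0 -> target item1 with weight 1
    net = np.zeros((3, 3))
    net[1, 0] = 1.0
    model = build_self_constructed(_study_with_network(net), "P01")
    assert model.A[1, 0] == 1.0
    assert np.count_nonzero(model.A) == 1
    np.testing.assert_array_equal(model.B, np.eye(3))
    # A x propagates the source value into the target
    np.testing.assert_allclose(model.A @ np.array([2.0, 0.0, 0.0]), [0.0, 2.0, 0.0])


def test_self_constructed_zero_network_predicts_bu():
    model = build_self_constructed(_study_with_network(np.zeros((3, 3))), "P01")
    u = input_vector(3, 1, -1.0)
    np.testing.assert_allclose(predict_post(model, np.array([3.0, 3.0, 3.0]), u), [0.0, -1.0, 0.0])


def test_missing_network_raises(cohort):
    study = cohort.study
    bare = StudyData(
        participants=study.participants,
        items=study.items,
        baseline=study.baseline,
        post=study.post,
        direction=study.direction,
        drawn_networks=None,
    )
    with pytest.raises(ModelError, match="no drawn network"):
        build_self_constructed(bare, study.participants[0])


def test_snapshot_structure(cohort):
    snap = assemble_snapshots(cohort.study, "P03")
    n = cohort.study.n_items
    assert snap.m == n
    assert np.linalg.matrix_rank(snap.X1) == 1
    assert np.linalg.matrix_rank(np.vstack([snap.X1, snap.U])) <= n + 1
    i = cohort.study.participant_index("P03")
    np.testing.assert_array_equal(snap.X2[:, 4], cohort.study.post[i, 4])


def test_snapshot_permutation_equivariance(cohort):
    snap = assemble_snapshots(cohort.study, "P01")
    perm = np.array([3, 0, 2, 1] + list(range(4, cohort.study.n_items)))
    permuted = SnapshotSet(X1=snap.X1[:, perm], X2=snap.X2[:, perm], U=snap.U[:, perm])
    model_a = dmdc_fit(snap)
    model_b = dmdc_fit(permuted)
    np.testing.assert_allclose(model_a.A, model_b.A, atol=1e-10)
    np.testing.assert_allclose(model_a.B, model_b.B, atol=1e-10)


def test_dmdc_recovers_true_system_full_rank(rng):
    n = 5
    A_true = rng.normal(size=(n, n)) * 0.3
    B_true = rng.normal(size=(n, n))
    snap = generate_full_rank_trajectory(A_true, B_true, m=3 * n, seed=5)
    model = dmdc_fit(snap)
    assert np.max(np.abs(model.A - A_true)) < 1e-8
    assert np.max(np.abs(model.B - B_true)) < 1e-8


def test_dmdc_training_reproduction_on_study_design(noisefree_cohort):
    study = noisefree_cohort.study
    for pid in study.participants[:5]:
        snap = assemble_snapshots(study, pid)
        model = dmdc_fit(snap)
        X2_hat = model.A @ snap.X1 + model.B @ snap.U
        np.testing.assert_allclose(X2_hat, snap.X2, atol=1e-9)


def test_dmdc_zero_states_canonical_inputs():
    n = 4
    X1 = np.zeros((n, n))
    U = np.eye(n)
    X2 = np.arange(n * n, dtype=float).reshape(n, n)
    model = dmdc_fit(SnapshotSet(X1=X1, X2=X2, U=U))
    np.testing.assert_allclose(model.A, 0.0, atol=1e-10)  # minimum-norm on the unexcited subspace
    np.testing.assert_allclose(model.B, X2, atol=1e-10)


def test_dmdc_is_least_squares_min_norm(rng):
    # oracle: numpy lstsq on the transposed system returns the same min-norm solution
    n, m = 4, 6
    X1 = rng.normal(size=(n, m))
    X2 = rng.normal(size=(n, m))
    U = rng.normal(size=(n, m))
    model = dmdc_fit(SnapshotSet(X1=X1, X2=X2, U=U))
    Z = np.vstack([X1, U])
    AB_oracle = np.linalg.lstsq(Z.T, X2.T, rcond=None)[0].T
    np.testing.assert_allclose(np.hstack([model.A, model.B]), AB_oracle, atol=1e-9)
    # residual optimality: no perturbation of the fit lowers the Frobenius residual
    AB = np.hstack([model.A, model.B])
    base = np.linalg.norm(X2 - AB @ Z)
    for _ in range(5):
        trial = AB + rng.normal(scale=1e-3, size=AB.shape)
        assert np.linalg.norm(X2 - trial @ Z) >= base - 1e-12


def test_predict_identity_and_pure_input():
    n = 3
    from psyctrl.models import DynamicalModel

    ident = DynamicalModel(A=np.eye(n), B=np.eye(n), provenance="dmdc")
    x0 = np.array([1.0, 2.0, 3.0])
    np.testing.assert_allclose(predict_post(ident, x0, np.zeros(n)), x0)
    zero = DynamicalModel(A=np.zeros((n, n)), B=np.eye(n), provenance="dmdc")
    np.testing.assert_allclose(predict_post(zero, x0, input_vector(n, 2, 1.0)), [0, 0, 1.0])


def test_cohort_predictions_reproduce_noisefree_observations(noisefree_cohort):
    study = noisefree_cohort.study
    pred, skipped = predict_cohort(study, "dmdc")
    assert skipped == []
    np.testing.assert_allclose(pred, study.post.astype(float), atol=1e-8)


def test_cohort_predictions_deterministic(cohort):
    a, _ = predict_cohort(cohort.study, "dmdc")
    b, _ = predict_cohort(cohort.study, "dmdc")
    np.testing.assert_array_equal(a, b)


def test_self_constructed_zero_networks_only_move_target():
    cfg = GeneratorConfig(n_participants=3, seed=11, draw_network_fidelity=0.0)
    sim = generate_cohort(cfg)
    study = sim.study
    # replace drawings with all-zero networks
    study.drawn_networks = {pid: np.zeros((study.n_items,) * 2) for pid in study.participants}
    pred, _ = predict_cohort(study, "self_constructed")
    for i in range(study.n_participants):
        for s in range(study.n_items):
            off = np.delete(pred[i, s], s)
            np.testing.assert_allclose(off, 0.0)
            assert pred[i, s, s] == study.direction[i, s]
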