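"""Network forward pass, evolutionary scoring/mutation, training, reports."""

import numpy as np
import pytest

from crmscan.cng import (
    CngParams,
    NeuralNet,
    TrainingSet,
    category_distance,
    ensemble_report,
    load_ensemble,
    mutate,
    random_net,
    run_training,
    save_ensemble,
    score,
    stats_to_point,
    train_cycle,
    VETO_SCORE,
)
from crmscan.positional import PositionalStats


def net_from(w, b_h, v, b_out):
    return NeuralNet(np.array(w, float), np.array(b_h, float), np.array(v, float), b_out)


def test_forward_conventions():
    zero = net_from([[0, 0, 0]], [0], [0], 0.0)
    # all-zero parameters: hidden 0.5, output h(0) = 1
    assert zero.forward([0.3, 0.5, 0.9]) == 1
    one = net_from([[1, 0, 0]], [0], [1], -0.9)
    # s(10) = 0.99995..., h(-0.9 + 0.99995) = 1
    assert one.forward([10, 0, 0]) == 1
    assert one.forward([-10, 0, 0]) == 0  # s(-10) ~ 0, h(-0.9) = 0


def oracle_forward(net, x):
    """Plain-arithmetic oracle for the forward pass."""
    import math

    acc = net.b_out
    for j in range(net.n_hidden):
        t = net.b_h[j]
        for k in range(3):
            t += net.w[j][k] * x[k]
        acc += net.v[j] * (1.0 / (1.0 + math.exp(-t)))
    return 1 if acc >= 0 else 0


def test_forward_matches_arithmetic_oracle():
    rng = np.random.default_rng(17)
    params = CngParams()
    for _ in range(30):
        net = random_net(params, rng)
        pts = np.column_stack(
            [rng.uniform(-1, 1, 20), rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)]
        )
        batch = net.includes(pts)
        for x, b in zip(pts, batch):
            o = oracle_forward(net, x)
            assert net.forward(x) == o == int(b)


@pytest.fixture(scope="module")
def two_cluster(fixtures):
    return fixtures["two-cluster"].training_set


def test_score_negative_veto_ratio_and_size(two_cluster):
    # a net accepting everything includes the negative controls -> veto
    accept_all = net_from([[0, 0, 0]], [0], [0], 1.0)
    assert score(accept_all, two_cluster) == VETO_SCORE
    # a net rejecting everything: no negatives, 0 positives, ratio 0
    reject_all = net_from([[0, 0, 0]], [0], [0], -1.0)
    s = score(reject_all, two_cluster)
    assert s[0] == 1 and s[1] == 0.0 and s[2] == 0
    assert s > VETO_SCORE  # any admissible net beats the veto score
    # ratio dominates, size breaks ties
    assert (1, 5.0, 12) > (1, 4.9, 100)
    assert (1, 5.0, 12) > (1, 5.0, 6)


def test_score_forced_coverage_gate(two_cluster):
    reject_all = net_from([[0, 0, 0]], [0], [0], -1.0)
    uncovered = np.ones(len(two_cluster.positives), dtype=bool)
    assert score(reject_all, two_cluster, uncovered) == VETO_SCORE


def test_mutate_contracts():
    rng = np.random.default_rng(23)
    params = CngParams(step=0.0)
    parent = random_net(params, rng)
    for _ in range(20):
        child = mutate(parent, rng, params, partner=parent)
        diff = np.flatnonzero(parent.flat() != child.flat())
        # crossover of identical parents is identical; point mutations with
        # step 0 change at most one parameter (the disruptive resample)
        assert diff.size <= 1
    params = CngParams(step=0.5)
    changed = [
        np.flatnonzero(parent.flat() != mutate(parent, rng, params).flat()).size
        for _ in range(20)
    ]
    assert all(c <= 1 for c in changed) and any(c == 1 for c in changed)


def test_training_set_validation():
    with pytest.raises(ValueError, match="negative control"):
        TrainingSet(np.array([[0.0, 1.0, 1.0]]), ["p"], np.empty((0, 3)))
    with pytest.raises(ValueError):
        TrainingSet(np.array([[0.1, 0.2]]), ["p"], np.empty((0, 2)))


def test_stats_to_point_neutral_fill():
    assert stats_to_point(PositionalStats(None, None, None, 0)) == (0.0, 1.0, 1.0)
    assert stats_to_point(PositionalStats(0.01, 0.5, -0.3, 9)) == (-0.3, 0.5, 0.01)


def test_train_cycle_on_separable_cluster(two_cluster):
    rng = np.random.default_rng(3)
    net, sc = train_cycle(two_cluster, CngParams(patience=10), rng)
    assert sc > VETO_SCORE
    pos_in = net.includes(two_cluster.positives)
    assert pos_in.sum() >= 15  # a real cluster, not a sliver
    assert not net.includes(two_cluster.negatives).any()


def test_run_training_covers_two_clusters(two_cluster, fixtures):
    rng = np.random.default_rng(12)
    ensemble = run_training(two_cluster, CngParams(), rng)
    assert ensemble.complete
    assert len(ensemble.networks) >= 2
    assert all(nets for nets in ensemble.coverage.values())
    report = ensemble_report(ensemble, two_cluster)
    dm = report["distance_matrix"].to_numpy()
    np.testing.assert_allclose(np.diag(dm), 0)
    np.testing.assert_allclose(dm, dm.T)
    # the two planted archetype clusters come back as distinct categories
    assert np.nanmax(dm) >= 0.8


def test_run_training_reproducible(two_cluster):
    e1 = run_training(two_cluster, CngParams(patience=5), np.random.default_rng(42))
    e2 = run_training(two_cluster, CngParams(patience=5), np.random.default_rng(42))
    assert [n.members for n in e1.networks] == [n.members for n in e2.networks]
    assert [n.score for n in e1.networks] == [n.score for n in e2.networks]


def test_category_distance_examples():
    assert category_distance({"a", "b"}, {"c"}) == 1.0
    assert category_distance({"a"}, {"a", "b", "c"}) == 0.0
    assert category_distance({"a", "b"}, {"a", "c"}) == 0.5
    assert category_distance(set(), {"a"}) is None


def test_ensemble_report_correlations(two_cluster):
    from crmscan.cng import EnsembleEntry, TrainedEnsemble

    params = CngParams()
    net = random_net(params, np.random.default_rng(0))
    single = TrainedEnsemble(
        [EnsembleEntry(net, [two_cluster.positive_keys[0]], (1, 1.0, 1), 0)],
        {two_cluster.positive_keys[0]: [0]},
        False,
    )
    rep = ensemble_report(single, two_cluster)
    assert rep["spearman"][0] is None  # single member: not computed
    # anti-monotone inputs give rho = -1
    keys = ["a", "b", "c"]
    pts = np.array([[-0.1, 0.1, 0.5], [-0.2, 0.2, 0.5], [-0.3, 0.3, 0.5]])
    ts = TrainingSet(pts, keys, np.empty((0, 3)))
    ens = TrainedEnsemble(
        [EnsembleEntry(net, keys, (1, 1.0, 3), 0)], {k: [0] for k in keys}, True
    )
    rho = ensemble_report(ens, ts)["spearman"][0]["bowley~distance_p"]
    assert rho == pytest.approx(-1.0)


def test_ensemble_save_load_roundtrip(tmp_path, two_cluster):
    ensemble = run_training(two_cluster, CngParams(patience=5), np.random.default_rng(2))
    path = tmp_path / "ensemble.json"
    save_ensemble(ensemble, path)
    back = load_ensemble(path)
    assert back.complete == ensemble.complete
    assert [n.members for n in back.networks] == [n.members for n in ensemble.networks]
    x = [0.1, 0.2, 0.3]
    assert back.networks[0].net.forward(x) == ensemble.networks[0].net.forward(x)
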