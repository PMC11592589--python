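import numpy as np
import pandas as pd
import pytest

from bnsens.evaluation import (
    EvaluationConfig,
    average_true_posterior,
    loo_accuracy,
    markov_blanket_experiment,
    pradhan_experiment,
    predict_class,
    resolve_targets,
    semantic_experiment,
    sigma_sweep,
)
from bnsens.learning import RecordDataset, impute_missing
from bnsens.network import CPT, Network, Variable, forward_sample, markov_blanket
from bnsens.noise import NoiseSpec
from bnsens.synthetic import (
    GeneratorConfig,
    bayes_optimal_accuracy,
    generate_network,
    make_benchmark,
)


@pytest.fixture(scope="module")
def truth():
    return generate_network(GeneratorConfig(seed=3))


@pytest.fixture(scope="module")
def data(truth):
    ds, normals = make_benchmark(truth, 250, seed=5)
    return impute_missing(ds, normals)


class TestPredictClass:
    def test_argmax_state(self, bayes_net):
        state, dist = predict_class(bayes_net, {"B": "t"}, "A")
        assert state == "t"
        assert dist[0] == pytest.approx(0.27 / 0.41)

    def test_exact_tie_goes_to_first_declared_state(self):
        net = Network(
            [Variable("A", ("t", "f"))], [CPT("A", (), [[0.5, 0.5]])]
        )
        state, _ = predict_class(net, {}, "A")
        assert state == "t"


class TestLooAccuracy:
    def test_noiseless_deterministic_gold_standard_is_perfect(self):
        net = Network(
            [Variable("dx", ("a", "b")), Variable("f", ("x", "y"))],
            [
                CPT("dx", (), [[0.5, 0.5]]),
                CPT("f", ("dx",), [[1.0, 0.0], [0.0, 1.0]]),
            ],
        )
        frame = forward_sample(net, 60, np.random.default_rng(1))
        ds = RecordDataset(frame=frame, class_variable="dx")
        acc, cases = loo_accuracy(net, ds, NoiseSpec("symmetric", 0.0))
        assert acc == 1.0
        assert all(c.correct for c in cases)

    def test_noiseless_accuracy_near_bayes_ceiling(self, truth):
        ds, normals = make_benchmark(truth, 1500, missing_rate=0.0, seed=11)
        acc, _ = loo_accuracy(
            truth.network, ds, NoiseSpec("symmetric", 0.0),
            EvaluationConfig(base_seed=1),
        )
        ceiling = bayes_optimal_accuracy(truth, method="exact").value
        assert abs(acc - ceiling) < 0.03

    def test_fixed_seed_reproducible(self, truth, data):
        cfg = EvaluationConfig(base_seed=77)
        spec = NoiseSpec("underconfidence", 1.0)
        a1, c1 = loo_accuracy(truth.network, data, spec, cfg)
        a2, c2 = loo_accuracy(truth.network, data, spec, cfg)
        assert a1 == a2
        for x, y in zip(c1, c2):
            np.testing.assert_array_equal(x.posterior, y.posterior)

    def test_accuracy_times_n_is_integer_and_matches_cases(self, truth, data):
        acc, cases = loo_accuracy(
            truth.network, data, NoiseSpec("symmetric", 1.0),
            EvaluationConfig(base_seed=3),
        )
        n_correct = sum(c.correct for c in cases)
        assert acc * data.n == pytest.approx(n_correct, abs=1e-9)

    def test_fast_and_generic_paths_agree_without_noise(self, truth):
        ds, normals = make_benchmark(truth, 40, missing_rate=0.0, seed=2)
        spec = NoiseSpec("symmetric", 0.0)
        fast, fc = loo_accuracy(
            truth.network, ds, spec, EvaluationConfig(base_seed=9)
        )
        evid = [n for n in truth.network.names if n != "disease"]
        slow, sc = loo_accuracy(
            truth.network, ds, spec,
            EvaluationConfig(base_seed=9, evidence_mode=evid),
        )
        assert fast == slow
        for a, b in zip(fc, sc):
            assert a.predicted_state == b.predicted_state
            np.testing.assert_allclose(a.posterior, b.posterior, atol=1e-9)

    def test_partial_evidence_runs_through_generic_path(self, truth):
        ds, normals = make_benchmark(truth, 20, missing_rate=0.0, seed=2)
        evid = [n for n in truth.network.names if n != "disease"][:3]
        acc, cases = loo_accuracy(
            truth.network, ds, NoiseSpec("symmetric", 0.5),
            EvaluationConfig(base_seed=4, evidence_mode=evid),
        )
        assert 0.0 <= acc <= 1.0
        assert len(cases) == 20

    def test_impossible_evidence_flagged_not_dropped(self):
        # pseudocount 0 and a held-out record with an unseen (class, finding)
        # combination makes that evidence impossible for every class state
        net = Network(
            [Variable("dx", ("a", "b")), Variable("f", ("x", "y", "z"))],
            [
                CPT("dx", (), [[0.5, 0.5]]),
                CPT("f", ("dx",), [[0.5, 0.25, 0.25], [0.25, 0.5, 0.25]]),
            ],
        )
        # record 2 holds the only f=z: leaving it out, P(z | dx) = 0 for both
        # class states, so its evidence is impossible under the learned model
        frame = pd.DataFrame(
            {"dx": ["a", "a", "a", "b", "b"], "f": ["x", "x", "z", "y", "y"]}
        )
        ds = RecordDataset(frame=frame, class_variable="dx")
        acc, cases = loo_accuracy(
            net, ds, NoiseSpec("symmetric", 0.0),
            EvaluationConfig(base_seed=0, pseudocount=0.0),
        )
        flagged = [c for c in cases if c.impossible]
        assert len(flagged) == 1 and flagged[0].index == 2
        assert not flagged[0].correct
        assert flagged[0].true_posterior == 0.0
        assert len(cases) == 5

    def test_average_true_posterior_consistent_with_cases(self, truth, data):
        cfg = EvaluationConfig(base_seed=21)
        spec = NoiseSpec("symmetric", 0.5)
        mtp = average_true_posterior(truth.network, data, spec, cfg)
        _, cases = loo_accuracy(truth.network, data, spec, cfg)
        assert mtp == pytest.approx(np.mean([c.true_posterior for c in cases]))


class TestSigmaSweep:
    def test_single_cell_equals_direct_call(self, truth, data):
        cfg = EvaluationConfig(
            sigma_grid=(0.0,), noise_types=("symmetric",), base_seed=5
        )
        res = sigma_sweep(truth.network, data, cfg)
        assert len(res.table) == 1
        acc, _ = loo_accuracy(
            truth.network, data, NoiseSpec("symmetric", 0.0), cfg
        )
        assert res.table.accuracy.iloc[0] == acc

    def test_row_count_is_grid_times_types_times_replicates(self, truth, data):
        cfg = EvaluationConfig(
            sigma_grid=(0.0, 0.5, 1.0), noise_types=("symmetric", "overconfidence"),
            replicates=2, base_seed=5, keep_cases=False,
        )
        res = sigma_sweep(truth.network, data, cfg)
        assert len(res.table) == 3 * 2 * 2

    def test_sigma_zero_invariant_to_noise_type_and_targets(self, truth, data):
        accs = set()
        for mode in ("all", "markov_blanket"):
            cfg = EvaluationConfig(
                sigma_grid=(0.0,), target_mode=mode, base_seed=8, keep_cases=False
            )
            res = sigma_sweep(truth.network, data, cfg)
            accs.update(res.table.accuracy.round(12))
        assert len(accs) == 1

    def test_bitwise_reproducible(self, truth, data):
        cfg = EvaluationConfig(sigma_grid=(0.0, 1.0), base_seed=123, keep_cases=False)
        a = sigma_sweep(truth.network, data, cfg).table
        b = sigma_sweep(truth.network, data, cfg).table
        pd.testing.assert_frame_equal(a, b)

    def test_per_case_results_regenerate_row_accuracy(self, truth, data):
        cfg = EvaluationConfig(sigma_grid=(1.0,), base_seed=6, replicates=2)
        res = sigma_sweep(truth.network, data, cfg)
        for _, row in res.table.iterrows():
            cases = res.cases[
                (row.sigma, row.noise_type, row.condition, row.replicate)
            ]
            assert np.mean([c.correct for c in cases]) == row.accuracy

    def test_summary_mentions_accuracy_table(self, truth, data):
        cfg = EvaluationConfig(sigma_grid=(0.0,), base_seed=5, keep_cases=False)
        out = sigma_sweep(truth.network, data, cfg).summary()
        assert "accuracy" in out and "symmetric" in out


class TestTargetResolution:
    def test_tag_targets(self, truth):
        label, targets = resolve_targets(
            truth.network, "tags:lab,disease", "disease", truth.tags
        )
        assert targets == {
            n for n, t in truth.tags.items() if t in ("lab", "disease")
        }

    def test_unknown_mode_raises(self, truth):
        with pytest.raises(ValueError):
            resolve_targets(truth.network, "everything", "disease")

    def test_explicit_unknown_variable_raises(self, truth):
        with pytest.raises(KeyError):
            resolve_targets(truth.network, "explicit:bogus", "disease")

    def test_blanket_and_complement_partition(self, truth):
        _, mb = resolve_targets(truth.network, "markov_blanket", "disease")
        _, comp = resolve_targets(truth.network, "non_markov_blanket", "disease")
        assert mb | comp | {"disease"} == set(truth.network.names)
        assert not mb & comp


class TestExperiments:
    def test_naive_bayes_blanket_condition_equals_all_nodes(self):
        truth = generate_network(
            GeneratorConfig(seed=19, extra_edge_density=0.0)
        )
        # pure class->finding edges: the class's blanket region covers the
        # whole network, so the blanket and all-node conditions share their
        # target set and (with condition-independent seeds) their results
        ds, normals = make_benchmark(truth, 120, missing_rate=0.0, seed=4)
        cfg = EvaluationConfig(sigma_grid=(0.0, 1.0), base_seed=31, keep_cases=False)
        res = markov_blanket_experiment(truth.network, ds, cfg)
        mb_set = markov_blanket(truth.network, "disease")
        assert mb_set == set(truth.network.names) - {"disease"}
        t = res.table
        assert set(t.condition) == {"markov_blanket", "non_markov_blanket", "all"}
        mb_rows = t[t.condition == "markov_blanket"].reset_index(drop=True)
        all_rows = t[t.condition == "all"].reset_index(drop=True)
        assert (mb_rows.accuracy == all_rows.accuracy).all()
        assert (
            mb_rows.mean_true_posterior == all_rows.mean_true_posterior
        ).all()

    def test_complement_noise_is_inert_under_complete_evidence(self):
        truth = _three_child_truth()
        ds, normals = make_benchmark(truth, 100, missing_rate=0.0, seed=9)
        cfg = EvaluationConfig(
            sigma_grid=(0.0, 1.0, 2.0), base_seed=13, keep_cases=False
        )
        res = markov_blanket_experiment(truth.network, ds, cfg)
        comp = res.table[res.table.condition == "non_markov_blanket"]
        for nt, sub in comp.groupby("noise_type"):
            assert sub.accuracy.nunique() == 1

    def test_semantic_conditions_cover_all_variables(self, truth, data):
        cfg = EvaluationConfig(sigma_grid=(0.0, 1.0), base_seed=2, keep_cases=False)
        res = semantic_experiment(truth.network, data, cfg, truth.tags)
        assert set(res.table.condition) == {"history", "physical", "lab", "disease"}
        covered = set()
        for tag in ("history", "physical", "lab", "disease"):
            _, targets = resolve_targets(
                truth.network, f"tags:{tag}", "disease", truth.tags
            )
            covered |= targets
        assert covered == set(truth.network.names)

    def test_untagged_variable_rejected(self, truth, data):
        tags = dict(truth.tags)
        tags.pop("h0")
        cfg = EvaluationConfig(sigma_grid=(0.0,), base_seed=2)
        with pytest.raises(ValueError, match="untagged"):
            semantic_experiment(truth.network, data, cfg, tags)

    def test_empty_tag_class_curve_is_flat(self):
        truth = generate_network(GeneratorConfig(seed=23, n_history=4,
                                                 n_physical=4, n_lab=1))
        net = truth.network
        tags = dict(truth.tags)
        # retag the lab node as physical: the lab condition is then empty
        tags["l8"] = "physical"
        ds, _ = make_benchmark(truth, 80, missing_rate=0.0, seed=3)
        cfg = EvaluationConfig(
            sigma_grid=(0.0, 2.0), noise_types=("symmetric",),
            base_seed=7, keep_cases=False,
        )
        res = semantic_experiment(net, ds, cfg, tags)
        lab = res.table[res.table.condition == "lab"]
        assert lab.accuracy.nunique() == 1

    def test_pradhan_average_hides_rank_flips(self, truth):
        ds, _ = make_benchmark(truth, 150, missing_rate=0.0, seed=12)
        cfg = EvaluationConfig(
            sigma_grid=(0.0, 0.5, 1.0), base_seed=41, keep_cases=True
        )
        res = pradhan_experiment(truth.network, ds, cfg)
        t = res.table
        mtp0 = t.loc[t.sigma == 0.0, "mean_true_posterior"].iloc[0]
        mtp05 = t.loc[t.sigma == 0.5, "mean_true_posterior"].iloc[0]
        assert abs(mtp05 - mtp0) < 0.1
        base = res.cases[(0.0, "symmetric", "all", 0)]
        high = res.cases[(1.0, "symmetric", "all", 0)]
        flips = sum(
            a.predicted_state != b.predicted_state for a, b in zip(base, high)
        )
        assert flips >= 1

    def test_case_posteriors_trajectories(self, truth):
        ds, _ = make_benchmark(truth, 30, missing_rate=0.0, seed=12)
        grid = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        cfg = EvaluationConfig(sigma_grid=grid, base_seed=41)
        res = pradhan_experiment(truth.network, ds, cfg)
        traj = res.case_posteriors("symmetric", "all")
        assert len(traj) == 30
        assert traj[0].shape == (len(grid), 4)
        np.testing.assert_allclose(traj[0].sum(axis=1), 1.0, atol=1e-9)


def _three_child_truth():
    """Gold standard whose class has exactly three children (a small Markov
    blanket) and several findings outside the blanket."""
    from bnsens.synthetic import generate_network

    for seed in range(200):
        cfg = GeneratorConfig(
            seed=seed, direct_child_fraction=0.25, extra_edge_density=0.0,
            n_history=4, n_physical=4, n_lab=4,
        )
        truth = generate_network(cfg)
        if len(markov_blanket(truth.network, "disease")) == 3:
            return truth
    raise RuntimeError("no 3-child topology found")
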