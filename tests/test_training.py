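"""Two-part likelihood, branch-length optimization, and the training loop."""

import numpy as np
import pytest

import shmconv as sc
from shmconv.models import RatePrediction
from shmconv.training import pair_loss_and_grads, placement_log_likelihood


def _uniform_rate_model(log_rate: float):
    model = sc.build_model(sc.ConvConfig(1, 1, 1, 0.0, "joined"), seed=0)
    model.params["rate_head.w"][:] = 0.0
    model.params["rate_head.b"][:] = log_rate
    return model


class TestSubstitutionProbability:
    def test_zero_branch_length(self):
        assert sc.substitution_probability(1.3, 0.0) == 0.0

    def test_closed_form_half(self):
        assert sc.substitution_probability(np.log(2.0), 1.0) == pytest.approx(0.5)

    def test_small_rate_limit(self):
        p = sc.substitution_probability(1e-6, 1.0)
        assert p == pytest.approx(1e-6, rel=1e-5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sc.substitution_probability(-1.0, 0.5)
        with pytest.raises(ValueError):
            sc.substitution_probability(1.0, -0.5)


class TestPcpLoss:
    def test_identity_pair_zero_branch_zero_loss(self):
        pcp = sc.ParentChildPair("ACGT", "ACGT", 0.0)
        pred = RatePrediction(
            rates=np.ones(4), csp=np.full((4, 4), 1 / 3), flagged=np.zeros(4, bool)
        )
        assert sc.pcp_loss(pred, pcp).total == 0.0

    def test_hand_computed_values(self):
        pcp = sc.ParentChildPair("A", "C", 1.0)
        rates = np.array([np.log(2.0)])  # p = 1 - exp(-ln 2) = 0.5
        sure = RatePrediction(rates, np.array([[0, 1.0, 0, 0]]), np.zeros(1, bool))
        lb = sc.pcp_loss(sure, pcp, csp_weight=0.01)
        assert lb.total == pytest.approx(0.693147, abs=1e-6)
        half = RatePrediction(rates, np.array([[0, 0.5, 0.5, 0]]), np.zeros(1, bool))
        lb2 = sc.pcp_loss(half, pcp, csp_weight=0.01)
        assert lb2.total == pytest.approx(0.700079, abs=1e-6)

    def test_zero_probability_child_base_is_infinite(self):
        pcp = sc.ParentChildPair("A", "C", 1.0)
        pred = RatePrediction(
            np.array([1.0]), np.array([[0, 0.0, 1.0, 0]]), np.zeros(1, bool)
        )
        lb = sc.pcp_loss(pred, pcp)
        assert np.isinf(lb.csp_nll) and lb.csp_nll > 0

    def test_additive_over_disjoint_site_subsets(self, tiny_dataset, small_model):
        _, ds = tiny_dataset
        pcp = ds[0]
        pred = small_model.predict_rates(pcp.parent)
        full = sc.pcp_loss(pred, pcp, 0.01)
        left = pcp.loss_mask.copy()
        left[len(pcp) // 2 :] = False
        right = pcp.loss_mask & ~left
        import dataclasses

        la = sc.pcp_loss(pred, dataclasses.replace(pcp, loss_mask=left), 0.01)
        lb = sc.pcp_loss(pred, dataclasses.replace(pcp, loss_mask=right), 0.01)
        assert la.total + lb.total == pytest.approx(full.total, rel=1e-12)

    def test_invariant_to_rate_time_rescaling(self):
        # only t * lambda matters: (lambda / c, c t) gives the same loss
        pcp = sc.ParentChildPair("ACGTAC", "ACTTAC", 0.08)
        rates = np.array([0.5, 1.0, 2.0, 3.0, 0.7, 1.4])
        csp = np.full((6, 4), 1 / 3)
        for i, b in enumerate(pcp.parent):
            csp[i, "ACGT".index(b)] = 0.0
        csp /= csp.sum(1, keepdims=True)
        a = sc.pcp_loss(RatePrediction(rates, csp, np.zeros(6, bool)), pcp)
        import dataclasses

        scaled = dataclasses.replace(pcp, branch_length=pcp.branch_length * 4.0)
        b = sc.pcp_loss(RatePrediction(rates / 4.0, csp, np.zeros(6, bool)), scaled)
        assert a.total == pytest.approx(b.total, rel=1e-12)


class TestOptimizeBranchLength:
    def test_uniform_rates_match_closed_form(self):
        model = _uniform_rate_model(0.4)
        lam = np.exp(0.4)
        pcp = sc.ParentChildPair("A" * 250, "C" * 6 + "A" * 244)
        t_star = sc.optimize_branch_length(model, pcp)
        assert t_star == pytest.approx(-np.log(1 - 6 / 250) / lam, abs=1e-6)

    def test_no_mutations_give_zero(self):
        model = _uniform_rate_model(0.0)
        assert sc.optimize_branch_length(model, sc.ParentChildPair("ACGT", "ACGT")) == 0.0

    def test_no_informative_sites_errors(self):
        with pytest.raises(ValueError):
            sc.optimize_branch_length(
                _uniform_rate_model(0.0), sc.ParentChildPair("NN", "NN")
            )

    def test_optimized_beats_normalized_offset(self, tiny_dataset, small_model):
        _, ds = tiny_dataset
        for pcp in ds:
            rates = small_model.predict_rates(pcp.parent).rates
            t_star = sc.optimize_branch_length(small_model, pcp, rates=rates)
            ll_star = placement_log_likelihood(rates, pcp, t_star)
            ll_norm = placement_log_likelihood(rates, pcp, pcp.branch_length)
            assert ll_star >= ll_norm - 1e-9


class TestGradients:
    @pytest.mark.parametrize("wiring", ["joined", "hybrid", "independent"])
    def test_numeric_vs_analytic(self, wiring):
        model = sc.build_model(sc.ConvConfig(3, 2, 3, 0.0, wiring), seed=3)
        pcp = sc.ParentChildPair("ACGTACGTAGCTNGCAT", "ACGAACGTAGCTNGCTT", 0.1)
        _, grads = pair_loss_and_grads(model, pcp, 0.01)
        eps = 1e-6
        for k, v in model.params.items():
            it = np.nditer(v, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = v[idx]
                v[idx] = orig + eps
                lp, _ = pair_loss_and_grads(model, pcp, 0.01)
                v[idx] = orig - eps
                lm, _ = pair_loss_and_grads(model, pcp, 0.01)
                v[idx] = orig
                num = (lp.total - lm.total) / (2 * eps)
                ana = grads[k][idx]
                if abs(num) > 1e-9 or abs(ana) > 1e-9:
                    assert ana == pytest.approx(num, rel=1e-4, abs=1e-8), k


class TestTrain:
    def _toy_config(self, **kw):
        base = dict(epochs=5, learning_rate=0.02, batch_size=4, seed=1)
        base.update(kw)
        return sc.TrainingConfig(**base)

    def test_same_seed_identical_weights(self, tiny_dataset):
        truth, ds = tiny_dataset
        runs = []
        for _ in range(2):
            model = sc.build_model(sc.ConvConfig(3, 2, 4, 0.2, "joined"), seed=5)
            sc.train(model, ds, None, self._toy_config())
            runs.append({k: v.copy() for k, v in model.params.items()})
        for k in runs[0]:
            assert np.array_equal(runs[0][k], runs[1][k])

    def test_empty_training_set_errors(self):
        ds = sc.PcpDataset([sc.ParentChildPair("ACGT", "ACGT")])  # 0 substitutions
        model = sc.build_model(sc.ConvConfig(1, 1, 1, 0.0, "joined"), seed=0)
        with pytest.raises(ValueError, match="empty"):
            sc.train(model, ds, None, self._toy_config())

    def test_separable_toy_reaches_entropy_floor(self):
        # one hot 3-mer always mutates, everything else never does; with
        # t = rho the placement loss can approach the Bernoulli entropy of
        # the labels, and a K=1 model is expressive enough to reach it
        rng = np.random.default_rng(0)
        pairs = []
        for _ in range(30):
            parent = "".join(rng.choice(list("ACGT"), size=60))
            child = "".join(
                ("G" if c == "A" else "A") if parent[i - 1 : i + 2] == "ACG" else c
                for i, c in enumerate(parent)
            )
            pairs.append(sc.ParentChildPair(parent, child))
        ds = sc.PcpDataset([p for p in pairs if sc.mutation_count(p) > 0])
        for p in ds:
            p.branch_length = sc.normalized_mutation_count(p)
        model = sc.build_model(sc.ConvConfig(1, 4, 8, 0.0, "joined"), seed=2)
        hist = sc.train(
            model, ds, None,
            self._toy_config(epochs=150, learning_rate=0.05, batch_size=8),
        )
        assert hist.train_placement_nll.iloc[-1] < hist.train_placement_nll.iloc[0]
        # entropy floor: mean per-pair Bernoulli entropy of the indicators
        floor = 0.0
        for p in ds:
            m, mask = sc.mutation_indicators(p)
            rho = m[mask].mean()
            n = mask.sum()
            floor += -n * (
                rho * np.log(rho) + (1 - rho) * np.log1p(-rho)
            ) / len(ds)
        assert hist.train_placement_nll.iloc[-1] < 1.25 * floor

    def test_history_shape_and_validation_columns(self, tiny_dataset):
        _, ds = tiny_dataset
        model = sc.build_model(sc.ConvConfig(3, 2, 3, 0.0, "joined"), seed=4)
        hist = sc.train(model, ds, ds, self._toy_config(epochs=3))
        assert list(hist.epoch) == [0, 1, 2]
        assert np.isfinite(hist.val_placement_nll).all()
        assert np.isfinite(hist.val_csp_nll).all()

    def test_joint_branch_opt_updates_offsets(self, tiny_dataset):
        _, ds = tiny_dataset
        before = [p.branch_length for p in ds]
        model = sc.build_model(sc.ConvConfig(1, 2, 3, 0.0, "joined"), seed=4)
        sc.train(model, ds, None, self._toy_config(epochs=2, joint_branch_opt=True))
        after = [p.branch_length for p in ds if sc.mutation_count(p) > 0]
        assert any(a != b for a, b in zip(after, before))

    def test_recovers_3mer_truth(self, recovery_experiment):
        """A K=1 model fit to 50k simulated sites ranks 3-mer rates like the truth."""
        _, _, report = recovery_experiment
        assert report.rate_rank_correlation > 0.95
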