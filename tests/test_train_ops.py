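"""Unit tests for each operation of the CMPL training loop."""

import dataclasses
from types import SimpleNamespace

import numpy as np
import pytest

from cmpl import nn
from cmpl._autodiff import Tensor, softmax
from cmpl.augmentation import AugmentationConfig
from cmpl.model import BackboneConfig, ModelOutput, build_model
from cmpl.synthetic_data import WindowSet
from cmpl.training import (
    EmbeddingState,
    PseudoLabelBatch,
    TrainConfig,
    assemble_batch,
    beta_schedule,
    clean_pseudo_labels,
    compute_h,
    consistency_loss,
    distance_loss,
    distance_scores,
    distance_scores_from_features,
    mpl_loss,
    pseudo_label,
    student_step,
    teacher_step,
    uda_loss,
    update_centroid,
    update_threshold,
)


class _ToyLinear:
    """Minimal stand-in for a backbone: logits = x @ W, features = x."""

    def __init__(self, weight):
        self.weight = Tensor(np.array(weight, dtype=float), requires_grad=True)
        self.cfg = SimpleNamespace(input_layout="1d")

    def forward(self, batch):
        x = Tensor(np.asarray(batch, dtype=float))
        return ModelOutput(features=x, logits=x @ self.weight)

    def parameters(self):
        return [self.weight]

    def get_state(self):
        return [self.weight.data.copy()]

    def set_state(self, state):
        self.weight.data = state[0].copy()


class TestAssembleBatch:
    def test_counts_and_determinism(self, prepared_pools, aug_cfg):
        labeled, unlabeled, _ = prepared_pools
        cfg = TrainConfig(batch_size=12)
        a = assemble_batch(labeled, unlabeled, cfg, aug_cfg, seed=4)
        b = assemble_batch(labeled, unlabeled, cfg, aug_cfg, seed=4)
        assert a.labeled_x.shape == (12, 100, 12)
        assert a.unlabeled_x.shape == (12, 100, 12)
        np.testing.assert_array_equal(a.labeled_x, b.labeled_x)
        np.testing.assert_array_equal(a.weak, b.weak)
        np.testing.assert_array_equal(a.strong, b.strong)

    def test_weak_view_differs_from_raw_when_jittered(self, prepared_pools):
        labeled, unlabeled, _ = prepared_pools
        cfg = TrainConfig(batch_size=8)
        aug = AugmentationConfig(jitter_sd=0.05)
        for seed in range(10):
            batch = assemble_batch(labeled, unlabeled, cfg, aug, seed=seed)
            assert not np.array_equal(batch.weak, batch.unlabeled_x)

    def test_empty_pool_rejected(self, prepared_pools, aug_cfg):
        labeled, _, _ = prepared_pools
        empty = WindowSet(np.empty((0, 100, 12)), np.empty(0, dtype=np.int64))
        with pytest.raises(ValueError):
            assemble_batch(labeled, empty, TrainConfig(), aug_cfg, seed=0)


class TestPseudoLabels:
    def test_hard_labels_are_argmax_with_low_index_ties(self):
        model = _ToyLinear(np.zeros((3, 6)))
        plb = pseudo_label(model, np.ones((4, 3)))
        # all-equal logits: tie broken toward class 0
        np.testing.assert_array_equal(plb.labels, 0)
        np.testing.assert_array_equal(plb.labels, np.argmax(plb.probs, axis=1))

    def test_biased_teacher_labels_everything_one_class(self):
        w = np.zeros((3, 6))
        w[:, 2] = 5.0
        plb = pseudo_label(_ToyLinear(w), np.ones((5, 3)))
        np.testing.assert_array_equal(plb.labels, 2)


class TestDistanceScores:
    def test_closed_form_values(self):
        state = EmbeddingState(centroid=np.array([1.0, 0.0]))
        feats = np.array([[1.0, 0.0], [1.0, 2.0]])
        np.testing.assert_allclose(distance_scores_from_features(feats, state), [0.0, 4.0])

    def test_matches_bruteforce_sum_of_squares(self, rng):
        feats = rng.normal(size=(20, 16))
        c = rng.normal(size=16)
        expected = [sum((f - c) ** 2) for f in feats]
        got = distance_scores_from_features(feats, EmbeddingState(centroid=c))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_uninitialized_centroid_rejected(self, rng):
        with pytest.raises(ValueError, match="centroid"):
            distance_scores_from_features(rng.normal(size=(2, 4)), EmbeddingState())

    def test_model_route_equals_feature_route(self, prepared_pools):
        labeled, _, _ = prepared_pools
        model = build_model(BackboneConfig(input_layout="4d"), 0)
        feats = model.forward(
            labeled.values[:6].reshape(6, 100, 4, 3)
        ).features.data
        state = EmbeddingState(centroid=feats.mean(axis=0))
        np.testing.assert_allclose(
            distance_scores(model, labeled.values[:6], state),
            distance_scores_from_features(feats, state),
        )


class TestCleaning:
    def _plb(self, scores):
        n = len(scores)
        return PseudoLabelBatch(
            probs=np.full((n, 6), 1 / 6),
            labels=np.arange(n) % 5,
            scores=np.asarray(scores, dtype=float),
        )

    def test_infinite_threshold_flags_nothing(self):
        state = EmbeddingState(centroid=np.zeros(2), threshold=np.inf)
        out = clean_pseudo_labels(self._plb([1.0, 2.0]), state, TrainConfig())
        assert not out.noise_mask.any()

    def test_zero_threshold_flags_all_positive_scores(self):
        state = EmbeddingState(centroid=np.zeros(2), threshold=0.0)
        out = clean_pseudo_labels(self._plb([0.5, 1.0]), state, TrainConfig())
        assert out.noise_mask.all()
        np.testing.assert_array_equal(out.labels, 5)

    def test_boundary_is_strict(self):
        # scores {1, 3, 5} at T = 3: only the 5 is flagged
        state = EmbeddingState(centroid=np.zeros(2), threshold=3.0)
        out = clean_pseudo_labels(self._plb([1.0, 3.0, 5.0]), state, TrainConfig())
        np.testing.assert_array_equal(out.noise_mask, [False, False, True])

    def test_exclude_mode_zeroes_weights_instead_of_relabeling(self):
        state = EmbeddingState(centroid=np.zeros(2), threshold=1.5)
        cfg = TrainConfig(noise_mode="exclude")
        out = clean_pseudo_labels(self._plb([1.0, 2.0]), state, cfg)
        np.testing.assert_array_equal(out.weights, [1.0, 0.0])
        assert out.labels[1] != 5

    def test_warmup_deactivation_behaves_as_infinite_threshold(self):
        state = EmbeddingState(centroid=np.zeros(2), threshold=0.0)
        out = clean_pseudo_labels(self._plb([1.0]), state, TrainConfig(), active=False)
        assert not out.noise_mask.any()


class TestStudentStep:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        model = _ToyLinear(np.eye(2))
        opt = nn.SGD(model.parameters(), lr=0.0)
        plb = PseudoLabelBatch(probs=np.full((3, 2), 0.5), labels=np.array([0, 1, 0]))
        loss = student_step(model, opt, np.random.default_rng(0).normal(size=(3, 2)), plb)
        assert loss is not None
        np.testing.assert_array_equal(model.weight.data, np.eye(2))

    def test_loss_decreases_after_one_small_step(self, rng):
        model = _ToyLinear(rng.normal(size=(4, 2)))
        opt = nn.SGD(model.parameters(), lr=0.01)
        x = rng.normal(size=(16, 4))
        plb = PseudoLabelBatch(probs=np.full((16, 2), 0.5), labels=rng.integers(0, 2, 16))
        first = student_step(model, opt, x, plb)
        second = float(nn.cross_entropy(model.forward(x).logits, plb.labels, plb.weights).data)
        assert second < first

    def test_update_matches_finite_difference_gradient(self, rng):
        w0 = rng.normal(size=(1, 2))
        x = rng.normal(size=(5, 1))
        labels = np.array([0, 1, 0, 1, 1])
        plb = PseudoLabelBatch(probs=np.full((5, 2), 0.5), labels=labels)
        eta = 0.05
        model = _ToyLinear(w0)
        student_step(model, nn.SGD(model.parameters(), lr=eta), x, plb)
        eps = 1e-6
        fd = np.zeros_like(w0)
        for i in range(2):
            for sign in (1, -1):
                w = w0.copy()
                w[0, i] += sign * eps
                fd[0, i] += sign * float(
                    nn.cross_entropy(_ToyLinear(w).forward(x).logits, labels).data
                )
        fd /= 2 * eps
        np.testing.assert_allclose(model.weight.data, w0 - eta * fd, atol=1e-4)

    def test_all_excluded_skips_the_step(self):
        model = _ToyLinear(np.eye(2))
        opt = nn.SGD(model.parameters(), lr=0.1)
        plb = PseudoLabelBatch(
            probs=np.full((2, 2), 0.5),
            labels=np.array([0, 1]),
            weights=np.zeros(2),
        )
        assert student_step(model, opt, np.ones((2, 2)), plb) is None
        np.testing.assert_array_equal(model.weight.data, np.eye(2))

    def test_excluded_windows_contribute_exactly_zero_gradient(self, rng):
        x = rng.normal(size=(6, 3))
        labels = rng.integers(0, 2, 6)
        keep = np.array([True, False, True, True, False, True])
        w = rng.normal(size=(3, 2))

        masked = _ToyLinear(w)
        loss = nn.cross_entropy(masked.forward(x).logits, labels, keep.astype(float))
        loss.backward()

        filtered = _ToyLinear(w)
        loss_f = nn.cross_entropy(filtered.forward(x[keep]).logits, labels[keep])
        loss_f.backward()
        # same per-sample contributions, different denominators (6 vs 4)
        np.testing.assert_allclose(
            masked.weight.grad, filtered.weight.grad * keep.sum() / keep.size, rtol=1e-12
        )


class TestFeedbackH:
    def test_identical_states_give_zero(self, rng):
        model = _ToyLinear(rng.normal(size=(2, 2)))
        state = model.get_state()
        x, y = rng.normal(size=(4, 2)), np.array([0, 1, 0, 1])
        assert compute_h(model, state, state, x, y) == 0.0

    def test_positive_when_student_improved(self, rng):
        # move weights along the negative gradient: labeled CE must drop
        x, y = rng.normal(size=(20, 2)), np.tile([0, 1], 10)
        model = _ToyLinear(np.zeros((2, 2)))
        before = model.get_state()
        loss = nn.cross_entropy(model.forward(x).logits, y)
        loss.backward()
        after = [before[0] - 0.5 * model.weight.grad]
        h = compute_h(model, before, after, x, y)
        assert h > 0

    def test_matches_independent_recomputation(self, rng):
        model = _ToyLinear(rng.normal(size=(3, 2)))
        s_before = [rng.normal(size=(3, 2))]
        s_after = [rng.normal(size=(3, 2))]
        x, y = rng.normal(size=(7, 3)), rng.integers(0, 2, 7)

        def ce(w):
            return float(nn.cross_entropy(Tensor(x @ w), y).data)

        expected = ce(s_before[0]) - ce(s_after[0])
        assert compute_h(model, s_before, s_after, x, y) == pytest.approx(expected, rel=1e-12)


class TestTeacherLosses:
    def test_mpl_loss_is_h_times_cross_entropy(self, rng):
        logits = Tensor(rng.normal(size=(5, 6)), requires_grad=True)
        labels = rng.integers(0, 6, 5)
        h = -0.37
        expected = h * float(nn.cross_entropy(Tensor(logits.data), labels).data)
        assert float(mpl_loss(h, logits, labels).data) == pytest.approx(expected, rel=1e-12)

    def test_zero_h_gives_zero_loss_and_gradient(self, rng):
        logits = Tensor(rng.normal(size=(4, 6)), requires_grad=True)
        loss = mpl_loss(0.0, logits, np.zeros(4, dtype=int))
        loss.backward()
        assert float(loss.data) == 0.0
        np.testing.assert_array_equal(logits.grad, 0.0)

    def test_teacher_gradient_flips_with_sign_of_h(self, rng):
        data = rng.normal(size=(4, 6))
        labels = rng.integers(0, 6, 4)
        grads = []
        for h in (0.8, -0.8):
            logits = Tensor(data.copy(), requires_grad=True)
            mpl_loss(h, logits, labels).backward()
            grads.append(logits.grad.copy())
        np.testing.assert_allclose(grads[0], -grads[1], rtol=1e-12)

    def test_consistency_equals_entropy_for_identical_predictions(self, rng):
        logits = rng.normal(size=(6, 6))
        probs = softmax(logits)
        got = float(consistency_loss(probs, Tensor(logits)).data)
        entropy = float((-(probs * np.log(probs)).sum(axis=1)).mean())
        assert got == pytest.approx(entropy, rel=1e-10)

    def test_consistency_of_uniform_teacher_is_log_six(self):
        uniform_logits = Tensor(np.zeros((3, 6)))
        uniform_probs = np.full((3, 6), 1 / 6)
        assert float(consistency_loss(uniform_probs, uniform_logits).data) == pytest.approx(
            np.log(6), rel=1e-12
        )

    def test_consistency_matches_bruteforce_cross_entropy(self, rng):
        weak = softmax(rng.normal(size=(8, 6)))
        strong_logits = rng.normal(size=(8, 6))
        strong_probs = softmax(strong_logits)
        brute = float(np.mean([-(w * np.log(s)).sum() for w, s in zip(weak, strong_probs)]))
        assert float(consistency_loss(weak, Tensor(strong_logits)).data) == pytest.approx(
            brute, rel=1e-10
        )

    def test_view_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            consistency_loss(softmax(rng.normal(size=(3, 6))), Tensor(rng.normal(size=(4, 6))))

    def test_uda_loss_is_supervised_ce_plus_consistency(self, rng):
        logits = Tensor(rng.normal(size=(5, 6)))
        y = rng.integers(0, 5, 5)
        ce = float(nn.cross_entropy(Tensor(logits.data), y).data)
        assert float(uda_loss(logits, y, 0.0).data) == pytest.approx(ce, rel=1e-12)
        assert float(uda_loss(logits, y, 1.25).data) == pytest.approx(ce + 1.25, rel=1e-12)

    def test_distance_loss_closed_forms(self):
        state = EmbeddingState(centroid=np.zeros(2))
        at_centroid = Tensor(np.zeros((3, 2)))
        assert float(distance_loss(at_centroid, state).data) == 0.0
        single = Tensor(np.array([[1.0, 0.0]]))
        assert float(distance_loss(single, state).data) == 1.0

    def test_distance_loss_matches_bruteforce_mean(self, rng):
        feats = rng.normal(size=(9, 5))
        c = rng.normal(size=5)
        state = EmbeddingState(centroid=c)
        brute = float(np.mean([((f - c) ** 2).sum() for f in feats]))
        assert float(distance_loss(Tensor(feats), state).data) == pytest.approx(brute, rel=1e-12)

    def test_combined_gradient_is_sum_of_component_gradients(self, rng):
        # autodiff linearity on a toy teacher whose features are x @ W
        x, y = rng.normal(size=(6, 3)), rng.integers(0, 2, 6)
        w = rng.normal(size=(3, 6))
        pseudo = rng.integers(0, 6, 6)
        state = EmbeddingState(centroid=rng.normal(size=6))
        grads = []
        for components in ("mpl", "uda", "dis", "all"):
            model = _ToyLinear(w)
            logits = Tensor(x) @ model.weight  # doubles as the feature map
            terms = {
                "mpl": mpl_loss(0.4, logits, pseudo),
                "uda": uda_loss(logits, y, 0.0),
                "dis": distance_loss(logits, state),
            }
            total = terms["mpl"] + terms["uda"] + terms["dis"] if components == "all" else terms[components]
            total.backward()
            grads.append(model.weight.grad.copy())
        np.testing.assert_allclose(grads[3], grads[0] + grads[1] + grads[2], atol=1e-10)


class TestEmbeddingUpdates:
    def test_centroid_full_step_jumps_to_batch_mean(self, rng):
        feats = rng.normal(size=(10, 4))
        state = EmbeddingState(centroid=rng.normal(size=4))
        update_centroid(state, feats, eta_c=1.0)
        np.testing.assert_allclose(state.centroid, feats.mean(axis=0), rtol=1e-12)

    def test_centroid_at_mean_is_a_fixed_point(self, rng):
        feats = rng.normal(size=(10, 4))
        state = EmbeddingState(centroid=feats.mean(axis=0).copy())
        update_centroid(state, feats, eta_c=0.3)
        np.testing.assert_allclose(state.centroid, feats.mean(axis=0), rtol=1e-12)

    def test_centroid_contraction_is_exactly_geometric(self, rng):
        feats = rng.normal(size=(6, 8))
        mean = feats.mean(axis=0)
        c0 = rng.normal(size=8)
        state = EmbeddingState(centroid=c0.copy())
        eta = 0.25
        update_centroid(state, feats, eta_c=eta)
        np.testing.assert_allclose(
            np.linalg.norm(state.centroid - mean),
            (1 - eta) * np.linalg.norm(c0 - mean),
            rtol=1e-12,
        )

    def test_centroid_learning_rate_bounds(self, rng):
        state = EmbeddingState(centroid=np.zeros(2))
        with pytest.raises(ValueError):
            update_centroid(state, rng.normal(size=(3, 2)), eta_c=0.0)
        with pytest.raises(ValueError):
            update_centroid(state, rng.normal(size=(3, 2)), eta_c=1.5)

    @pytest.mark.parametrize("alpha,expected_mu", [(1.0, 3.0), (0.0, None), (0.25, 0.25 * 3.0 + 0.75 * 1.0)])
    def test_threshold_ema(self, alpha, expected_mu):
        state = EmbeddingState(centroid=np.zeros(2), mu=1.0, sigma=0.5)
        scores = np.array([2.0, 3.0, 4.0])  # mean 3, std sqrt(2/3)
        update_threshold(state, scores, alpha=alpha, beta_t=2.0)
        mu = expected_mu if expected_mu is not None else 1.0
        sigma = alpha * scores.std() + (1 - alpha) * 0.5
        assert state.mu == pytest.approx(mu, rel=1e-12)
        assert state.sigma == pytest.approx(sigma, rel=1e-12)
        assert state.threshold == pytest.approx(state.mu + 2.0 * state.sigma, rel=1e-12)

    def test_threshold_arithmetic_example(self):
        # mu = 2.0, sigma = 0.5, beta = 2 -> T = 3.0
        state = EmbeddingState(centroid=np.zeros(1))
        update_threshold(state, np.array([2.0]), alpha=1.0, beta_t=2.0)
        assert state.mu == 2.0 and state.sigma == 0.0
        state.sigma = 0.5
        state.threshold = state.mu + state.beta * state.sigma
        assert state.threshold == 3.0

    def test_beta_schedule_linear_endpoints_and_midpoint(self):
        cfg = TrainConfig(total_steps=1001, beta_start=0.5, beta_end=2.5)
        assert beta_schedule(cfg, 0) == 0.5
        assert beta_schedule(cfg, 1000) == 2.5
        assert beta_schedule(cfg, 500) == pytest.approx(1.5)
        betas = [beta_schedule(cfg, s) for s in range(0, 1001, 50)]
        assert all(b2 >= b1 for b1, b2 in zip(betas, betas[1:]))


class TestTeacherStep:
    def test_zero_learning_rate_leaves_teacher_unchanged(self, rng):
        model = _ToyLinear(rng.normal(size=(2, 2)))
        before = model.get_state()
        opt = nn.SGD(model.parameters(), lr=0.0)
        loss = nn.cross_entropy(model.forward(rng.normal(size=(3, 2))).logits, np.array([0, 1, 0]))
        teacher_step(opt, loss, None)
        np.testing.assert_array_equal(model.weight.data, before[0])

    def test_non_finite_loss_aborts_with_diagnostics(self):
        bad = Tensor(np.array(np.inf))
        with pytest.raises(FloatingPointError):
            teacher_step(nn.SGD([], lr=0.1), bad, "diagnostic breakdown")
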