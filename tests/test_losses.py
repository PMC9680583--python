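"""Unit values, reduction relations, monotonicity and numerical stability
of every loss term, plus the composite objectives of the three model kinds."""

import numpy as np
import pytest

from sctsynth.losses import (
    LossWeights, cut_generator_objective, cyclecut_generator_objective,
    cyclegan_generator_objective, d_nce_cross_entropy_dpos,
    discriminator_objective, l1_mean, lsgan_dis_loss, lsgan_gen_loss,
    nce_cross_entropy, patchnce_loss,
)
from sctsynth.nn.networks import FeatureStack


def test_default_weights_are_standard_protocol_values():
    w = LossWeights()
    assert (w.alpha, w.beta) == (10.0, 5.0)
    assert (w.lambda1, w.lambda2) == (1.0, 1.0)
    assert (w.eta1, w.eta2, w.eta3, w.eta4) == (1.0, 1.0, 1.0, 1.0)
    assert w.tau == 0.07


def test_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(alpha=-1)
    with pytest.raises(ValueError):
        LossWeights(tau=0.0)


class TestLSGAN:
    @pytest.mark.parametrize("scores,expected", [
        (np.array([1.0]), 0.0),
        (np.array([0.0]), 1.0),
        (np.array([0.5, 0.5]), 0.25),
    ])
    def test_generator_values(self, scores, expected):
        assert lsgan_gen_loss(scores) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("real,fake,expected", [
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 1.0),
        (0.5, 0.5, 0.25),
    ])
    def test_discriminator_values(self, real, fake, expected):
        got = lsgan_dis_loss(np.array([real]), np.array([fake]))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lsgan_gen_loss(np.array([]))
        with pytest.raises(ValueError):
            lsgan_dis_loss(np.array([]), np.array([0.5]))

    def test_score_map_lists_are_averaged(self):
        maps = [np.full((2, 2), 0.5), np.full((3, 3), 0.5)]
        assert lsgan_gen_loss(maps) == pytest.approx(0.25)


class TestL1:
    def test_identical_is_zero(self):
        a = np.arange(6.0).reshape(2, 3)
        assert l1_mean(a, a) == 0.0

    def test_constant_offset(self):
        a = np.zeros((4, 4))
        assert l1_mean(a, a + 0.2) == pytest.approx(0.2)

    def test_hand_example(self):
        assert l1_mean(np.array([0.0, 1.0]), np.array([1.0, 3.0])) == \
            pytest.approx(1.5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_mean(np.zeros(3), np.zeros(4))


class TestNCECrossEntropy:
    def test_uniform_similarities_give_log_count(self):
        # equal positive and 255 equal negatives -> uniform softmax
        assert nce_cross_entropy(0.3, [0.3] * 255, 0.07) == \
            pytest.approx(np.log(256), rel=1e-12)

    def test_confident_positive_near_zero(self):
        got = nce_cross_entropy(1.0, [0.0], 0.07)
        expected = np.log(1 + np.exp(-1 / 0.07))
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(6.2e-7, rel=0.02)

    def test_strictly_decreasing_in_positive_similarity(self):
        negs = [0.2, -0.4, 0.1]
        vals = [nce_cross_entropy(p, negs, 0.07)
                for p in (-1.0, -0.5, 0.0, 0.5, 1.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            nce_cross_entropy(0.5, [0.1], 0.0)

    def test_finite_at_similarity_extremes(self):
        for pos in (-1.0, 1.0):
            for neg in (-1.0, 1.0):
                v = nce_cross_entropy(pos, [neg] * 255, 0.07)
                assert np.isfinite(v) and v > 0

    def test_analytic_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            pos = rng.uniform(-1, 1)
            negs = rng.uniform(-1, 1, size=8)
            eps = 1e-6
            fd = (nce_cross_entropy(pos + eps, negs, 0.07)
                  - nce_cross_entropy(pos - eps, negs, 0.07)) / (2 * eps)
            an = d_nce_cross_entropy_dpos(pos, negs, 0.07)
            assert an == pytest.approx(fd, abs=1e-4)


def _orthonormal_stack(s, d, layer=1, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(d, d)))
    vecs = q[:s]
    return FeatureStack(features={layer: vecs},
                        locations={layer: np.arange(s)})


class TestPatchNCE:
    def test_identical_orthogonal_stacks_near_zero(self):
        s = 16
        stack = _orthonormal_stack(s, 32)
        loss = patchnce_loss(stack, stack, 0.07)
        expected = np.log(1 + (s - 1) * np.exp(-1 / 0.07))
        assert loss == pytest.approx(expected, rel=1e-9)
        assert loss < 1e-5

    def test_random_output_stack_near_log_s(self):
        """Independent unit-vector outputs give ~log S on average (the
        uniform-similarity regime); high feature dimension keeps random
        similarities near zero."""
        rng = np.random.default_rng(42)
        s, d, reps = 16, 4096, 200
        vals = []
        base = _orthonormal_stack(s, d)
        for _ in range(reps):
            out_vecs = rng.normal(size=(s, d))
            out_vecs /= np.linalg.norm(out_vecs, axis=1, keepdims=True)
            out = FeatureStack(features={1: out_vecs},
                               locations={1: np.arange(s)})
            vals.append(patchnce_loss(base, out, 0.07))
        se = np.std(vals, ddof=1) / np.sqrt(reps)
        assert np.mean(vals) == pytest.approx(np.log(s), abs=3 * max(se, 0.05))

    def test_negative_enumeration_order_irrelevant(self):
        rng = np.random.default_rng(1)
        s, d = 10, 8
        z = rng.normal(size=(s, d))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        zh = rng.normal(size=(s, d))
        zh /= np.linalg.norm(zh, axis=1, keepdims=True)
        locs = np.arange(s)
        a = patchnce_loss(FeatureStack({1: z}, {1: locs}),
                          FeatureStack({1: zh}, {1: locs}), 0.07)
        # permute rows of both stacks together: the same set of
        # positive/negative similarities enumerated in a different order
        perm = rng.permutation(s)
        b = patchnce_loss(FeatureStack({1: z[perm]}, {1: locs[perm]}),
                          FeatureStack({1: zh[perm]}, {1: locs[perm]}), 0.07)
        assert a == pytest.approx(b, abs=1e-6)

    def test_location_record_mismatch_rejected(self):
        a = _orthonormal_stack(4, 8)
        b = FeatureStack(features=dict(a.features),
                         locations={1: np.array([0, 1, 2, 9])})
        with pytest.raises(ValueError, match="location"):
            patchnce_loss(a, b, 0.07)

    def test_layer_mismatch_rejected(self):
        a = _orthonormal_stack(4, 8, layer=1)
        b = _orthonormal_stack(4, 8, layer=2)
        with pytest.raises(ValueError, match="layer"):
            patchnce_loss(a, b, 0.07)


class TestObjectives:
    def test_cyclegan_hand_arithmetic(self):
        parts = dict(adversarial_a=1.0, adversarial_b=1.0, cycle_mri=0.1,
                     cycle_ct=0.1, identity_ct=0.2, identity_mri=0.2)
        rep = cyclegan_generator_objective(parts, LossWeights())
        assert rep.total == pytest.approx(6.0, rel=1e-12)

    def test_cyclegan_all_zero(self):
        parts = {k: 0.0 for k in ("adversarial_a", "adversarial_b", "cycle_mri",
                                  "cycle_ct", "identity_ct", "identity_mri")}
        assert cyclegan_generator_objective(parts, LossWeights()).total == 0.0

    def test_doubling_alpha_doubles_only_cycle_contribution(self):
        parts = dict(adversarial_a=0.3, adversarial_b=0.4, cycle_mri=0.1,
                     cycle_ct=0.2, identity_ct=0.05, identity_mri=0.06)
        t1 = cyclegan_generator_objective(parts, LossWeights(alpha=10)).total
        t2 = cyclegan_generator_objective(parts, LossWeights(alpha=20)).total
        assert t2 - t1 == pytest.approx(10 * (0.1 + 0.2), rel=1e-9)

    def test_cut_hand_arithmetic(self):
        rep = cut_generator_objective(
            dict(adversarial_a=0.5, nce_1=2.0, nce_2=1.0), LossWeights())
        assert rep.total == pytest.approx(3.5)

    def test_cut_lambda2_removes_identity_nce(self):
        parts = dict(adversarial_a=0.5, nce_1=2.0, nce_2=1.0)
        t = cut_generator_objective(parts, LossWeights(lambda2=0.0)).total
        assert t == pytest.approx(2.5)

    def test_cyclecut_hand_arithmetic(self):
        parts = dict(adversarial_a=1.0, adversarial_b=1.0, cycle_mri=0.1,
                     cycle_ct=0.1, identity_ct=0.2, identity_mri=0.2,
                     nce_1=1.0, nce_2=1.0, nce_3=1.0, nce_4=1.0)
        rep = cyclecut_generator_objective(parts, LossWeights())
        assert rep.total == pytest.approx(10.0, rel=1e-12)

    def test_missing_component_rejected(self):
        with pytest.raises(KeyError):
            cyclegan_generator_objective({"adversarial_a": 1.0}, LossWeights())
        with pytest.raises(KeyError):
            cyclecut_generator_objective(
                dict(adversarial_a=1.0, adversarial_b=1.0, cycle_mri=0.1,
                     cycle_ct=0.1, identity_ct=0.2, identity_mri=0.2,
                     nce_1=1.0, nce_2=1.0, nce_3=1.0), LossWeights())

    def test_total_is_weighted_sum_of_reported_components(self):
        rng = np.random.default_rng(5)
        parts = {k: float(rng.uniform(0, 2)) for k in
                 ("adversarial_a", "adversarial_b", "cycle_mri", "cycle_ct",
                  "identity_ct", "identity_mri", "nce_1", "nce_2", "nce_3",
                  "nce_4")}
        w = LossWeights()
        rep = cyclecut_generator_objective(parts, w)
        manual = (rep.components["adversarial_a"] + rep.components["adversarial_b"]
                  + w.alpha * (rep.components["cycle_mri"] + rep.components["cycle_ct"])
                  + w.beta * (rep.components["identity_ct"] + rep.components["identity_mri"])
                  + rep.components["nce_1"] + rep.components["nce_2"]
                  + rep.components["nce_3"] + rep.components["nce_4"])
        assert rep.total == pytest.approx(manual, rel=1e-9)


class TestReductionRelations:
    def _random_parts(self, seed):
        rng = np.random.default_rng(seed)
        return {k: float(rng.uniform(0, 3)) for k in
                ("adversarial_a", "adversarial_b", "cycle_mri", "cycle_ct",
                 "identity_ct", "identity_mri", "nce_1", "nce_2", "nce_3",
                 "nce_4")}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cyclecut_with_zero_eta_equals_cyclegan(self, seed):
        parts = self._random_parts(seed)
        w0 = LossWeights(eta1=0, eta2=0, eta3=0, eta4=0)
        full = cyclecut_generator_objective(parts, w0).total
        base = cyclegan_generator_objective(parts, LossWeights()).total
        assert full == pytest.approx(base, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cut_equals_one_directional_restriction(self, seed):
        """The CUT objective is the cycleCUT restricted to the forward
        direction: adversarial A plus the two forward NCE terms, with
        cycle/identity weights zeroed and the reverse direction ignored."""
        parts = self._random_parts(seed)
        cut_parts = dict(adversarial_a=parts["adversarial_a"],
                         nce_1=parts["nce_1"], nce_2=parts["nce_2"])
        w0 = LossWeights(alpha=0, beta=0, eta3=0, eta4=0)
        restricted = (cyclecut_generator_objective(parts, w0).total
                      - parts["adversarial_b"])
        assert cut_generator_objective(cut_parts, LossWeights()).total == \
            pytest.approx(restricted, rel=1e-9)


class TestDiscriminatorObjective:
    def test_two_discriminator_sum(self):
        rep = discriminator_objective("cyclecut", {"d_a": 0.3, "d_b": 0.2})
        assert rep.total == pytest.approx(0.5)

    def test_cut_single_discriminator(self):
        assert discriminator_objective("cut", {"d_a": 0.3}).total == \
            pytest.approx(0.3)

    def test_component_mismatch_rejected(self):
        with pytest.raises(KeyError):
            discriminator_objective("cyclegan", {"d_a": 0.3})
        with pytest.raises(KeyError):
            discriminator_objective("cut", {"d_a": 0.3, "d_b": 0.1})
        with pytest.raises(ValueError):
            discriminator_objective("pix2pix", {"d_a": 0.3})
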