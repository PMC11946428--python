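"""Structural re-parameterization: norm folding, branch merging, and whole
unit/network deploy equivalence, each checked against the unfused forward."""
import warnings

import numpy as np
import pytest

from hepaseg import reparam
from hepaseg.network import RepUnit, build_network, tiny_config
from hepaseg.nn import Tensor, no_grad
from hepaseg.nn import functional as F


def rand_branch(rng, co=4, ci=4, k=3, with_norm=True):
    norm = None
    if with_norm:
        norm = reparam.NormStats(mean=rng.standard_normal(co),
                                 var=rng.random(co) + 0.5,
                                 gamma=rng.standard_normal(co),
                                 beta=rng.standard_normal(co), eps=1e-5)
    return reparam.BranchWeights(
        kernel=rng.standard_normal((co, ci, k, k, k)) * 0.2,
        bias=rng.standard_normal(co), norm=norm)


def branch_forward(branch, x):
    """Reference forward: convolution then explicit normalization."""
    out = F.conv3d(Tensor(x), Tensor(branch.kernel.astype(np.float32)),
                   Tensor(branch.bias.astype(np.float32)),
                   padding=branch.kernel.shape[2] // 2).data
    st = branch.norm
    if st is not None:
        scale = (st.gamma / np.sqrt(st.var + st.eps)).astype(np.float32)
        out = (out - st.mean.reshape(1, -1, 1, 1, 1)) \
            * scale.reshape(1, -1, 1, 1, 1) + st.beta.reshape(1, -1, 1, 1, 1)
    return out


class TestFuseNorm:
    def test_identity_statistics_leave_kernel_unchanged(self):
        rng = np.random.default_rng(0)
        b = rand_branch(rng)
        b.norm = reparam.NormStats(np.zeros(4), np.ones(4), np.ones(4),
                                   np.zeros(4), eps=0.0)
        fused = reparam.fuse_norm(b)
        np.testing.assert_allclose(fused.kernel, b.kernel)
        np.testing.assert_allclose(fused.bias, b.bias)

    def test_fused_forward_matches_unfused(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            b = rand_branch(rng)
            fused = reparam.fuse_norm(b)
            x = rng.standard_normal((1, 4, 5, 5, 5)).astype(np.float32)
            np.testing.assert_allclose(branch_forward(fused, x),
                                       branch_forward(b, x), atol=1e-5)

    def test_zero_mean_stats_shift_bias_by_beta(self):
        rng = np.random.default_rng(2)
        b = rand_branch(rng)
        beta = b.norm.beta
        gamma = b.norm.gamma
        b.norm.mean = np.zeros(4)
        b.norm.var = np.ones(4)
        b.norm.eps = 0.0
        fused = reparam.fuse_norm(b)
        np.testing.assert_allclose(fused.bias, b.bias * gamma + beta,
                                   atol=1e-12)

    def test_requires_norm_and_positive_variance(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            reparam.fuse_norm(rand_branch(rng, with_norm=False))
        b = rand_branch(rng)
        b.norm.var = -np.ones(4)
        b.norm.eps = 0.0
        with pytest.raises(ValueError):
            reparam.fuse_norm(b)


class TestMergeBranches:
    def test_two_pointwise_branches_sum_at_center(self):
        rng = np.random.default_rng(4)
        b1 = rand_branch(rng, k=1, with_norm=False)
        b2 = rand_branch(rng, k=1, with_norm=False)
        merged = reparam.merge_branches([b1, b2], target_size=1)
        np.testing.assert_allclose(merged.kernel, b1.kernel + b2.kernel)

    def test_conv_plus_identity_adds_center_delta(self):
        rng = np.random.default_rng(5)
        b = rand_branch(rng, k=3, with_norm=False)
        ident = reparam.identity_branch(4)
        merged = reparam.merge_branches([b, ident], target_size=3)
        x = rng.standard_normal((2, 4, 6, 6, 6)).astype(np.float32)
        ref = branch_forward(b, x) + x
        np.testing.assert_allclose(branch_forward(merged, x), ref, atol=1e-5)
        # delta sits at the kernel center on the channel diagonal
        np.testing.assert_allclose(
            merged.kernel[:, :, 1, 1, 1] - b.kernel[:, :, 1, 1, 1], np.eye(4))

    def test_single_branch_at_target_size_is_identity(self):
        rng = np.random.default_rng(6)
        b = rand_branch(rng, with_norm=False)
        merged = reparam.merge_branches([b], target_size=3)
        np.testing.assert_allclose(merged.kernel, b.kernel)

    def test_mixed_sizes_merge_exactly(self):
        rng = np.random.default_rng(7)
        b3 = rand_branch(rng, k=3, with_norm=False)
        b1 = rand_branch(rng, k=1, with_norm=False)
        merged = reparam.merge_branches([b3, b1, reparam.identity_branch(4)],
                                        target_size=3)
        x = rng.standard_normal((1, 4, 7, 7, 7)).astype(np.float32)
        ref = branch_forward(b3, x) + branch_forward(b1, x) + x
        np.testing.assert_allclose(branch_forward(merged, x), ref, atol=1e-5)

    def test_errors(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            reparam.merge_branches([])
        with pytest.raises(ValueError):
            reparam.merge_branches([rand_branch(rng, with_norm=True)])
        with pytest.raises(ValueError):
            reparam.merge_branches([rand_branch(rng, co=4, with_norm=False),
                                    rand_branch(rng, co=5, with_norm=False)])
        with pytest.raises(ValueError):
            reparam.BranchWeights(kernel=np.zeros((2, 2, 2, 2, 2)))


class TestUnitAndModelDeploy:
    def _settled_unit(self, width, seed):
        rng = np.random.default_rng(seed)
        unit = RepUnit(width, rng=rng)
        unit.train()
        for _ in range(3):
            unit(Tensor(rng.standard_normal(
                (2, width, 6, 6, 6)).astype(np.float32)))
        unit.eval()
        return unit, rng

    @pytest.mark.parametrize("width", [4, 16])
    def test_unit_fusion_matches_eval_forward(self, width):
        unit, rng = self._settled_unit(width, width)
        xs = [rng.standard_normal((1, width, 5, 5, 5)).astype(np.float32)
              for _ in range(5)]
        with no_grad():
            before = [unit(Tensor(x)).data for x in xs]
        unit.reparameterize()
        with no_grad():
            after = [unit(Tensor(x)).data for x in xs]
        for a, b in zip(before, after):
            assert np.abs(a - b).max() < 1e-5

    def test_zero_kernels_leave_bias_constant_field(self):
        width = 3
        unit, _ = self._settled_unit(width, 0)
        unit.conv3.weight.data[...] = 0
        unit.conv1.weight.data[...] = 0
        # closed form: with zero kernels each conv branch contributes the
        # normalized bias; the identity branch normalizes the input
        x = np.zeros((1, width, 4, 4, 4), np.float32)
        with no_grad():
            out = unit(Tensor(x)).data

        def norm(v, bn):
            return (v - bn.running_mean) * bn.weight.data / np.sqrt(
                bn.running_var + bn.eps) + bn.bias.data

        expect = np.maximum(norm(unit.conv3.bias.data, unit.bn3)
                            + norm(unit.conv1.bias.data, unit.bn1)
                            + norm(np.zeros(width), unit.bnid), 0)
        np.testing.assert_allclose(out[0, :, 2, 2, 2], expect, atol=1e-5)

    def test_model_deploy_equivalence_and_param_drop(self):
        from hepaseg.network import settle_norm_stats
        from hepaseg.reparam import convert_to_deploy, equivalence_report
        rng = np.random.default_rng(9)
        model = build_network(tiny_config(), seed=9)
        settle_norm_stats(model, rng.standard_normal(
            (1, 1, 32, 32, 16)).astype(np.float32))
        deployed = build_network(tiny_config(), seed=9)
        deployed.load_state_dict(model.state_dict())
        p_before = deployed.num_parameters()
        convert_to_deploy(deployed)
        assert deployed.num_parameters() < p_before
        rep = equivalence_report(model, deployed, shape=(1, 1, 32, 32, 16),
                                 n_probes=5, seed=10)
        assert rep["max_abs_dev"] < 1e-4

    def test_deploy_is_idempotent_with_warning(self):
        from hepaseg.reparam import convert_to_deploy
        model = build_network(tiny_config(), seed=1)
        convert_to_deploy(model)
        state = {k: v.copy() for k, v in model.state_dict().items()}
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            convert_to_deploy(model)
        assert any("already" in str(w.message) for w in rec)
        after = model.state_dict()
        assert all(np.array_equal(state[k], after[k]) for k in state)
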