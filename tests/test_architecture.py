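"""Analytic shape/parameter chain, variants, feasibility, builder equivalence."""

import numpy as np
import pytest

from afdetect1d import (
    FeasibilityError,
    VARIANT_NAMES,
    build_network,
    check_feasible,
    compute_layer_summaries,
    count_total,
    count_trainable,
    describe,
    make_variant,
)

CANONICAL_CONV_LENGTHS = [8996, 4494, 2243, 1117, 554, 273, 132, 62, 27, 9]
CANONICAL_CHANNELS = [32, 32, 64, 64, 128, 128, 256, 256, 512, 512]
CANONICAL_PARAM_ROWS = [192, 128, 5152, 10_304, 20_544, 41_088, 82_048,
                        164_096, 327_936, 655_872, 1_311_232, 589_952, 4128, 132]


class TestCanonicalStack:
    def test_conv_output_chain(self):
        rows = compute_layer_summaries(make_variant("Proposed-1"))
        convs = [r for r in rows if r.layer_kind == "conv"]
        assert [r.output_len for r in convs] == CANONICAL_CONV_LENGTHS
        assert [r.channels for r in convs] == CANONICAL_CHANNELS

    def test_per_layer_parameter_rows(self):
        rows = compute_layer_summaries(make_variant("Proposed-1"))
        assert [r.params_total for r in rows if r.params_total] == CANONICAL_PARAM_ROWS

    def test_bn_trainable_split(self):
        rows = compute_layer_summaries(make_variant("Proposed-1"))
        bn = next(r for r in rows if r.layer_kind == "bn")
        assert (bn.params_total, bn.params_trainable) == (128, 64)

    def test_totals(self):
        spec = make_variant("Proposed-1")
        assert count_total(spec) == 3_212_804
        assert count_trainable(spec) == 3_212_740


class TestVariants:
    @pytest.mark.parametrize("name,expected", [
        ("Proposed-1", 3_212_740),
        ("Proposed-2", 3_212_740),
        ("All-BN", 3_216_644),
        ("No-BN", 3_212_676),
        ("Maxpooling", 2_885_060),
        ("Max-Average", 2_885_060),
        ("Extra-Average", 2_885_060),
    ])
    def test_trainable_totals(self, name, expected):
        assert count_trainable(make_variant(name)) == expected

    def test_bn_placement(self):
        assert [b.has_bn for b in make_variant("Proposed-1").blocks] == \
            [True] + [False] * 9
        assert all(b.has_bn for b in make_variant("All-BN").blocks)
        assert not any(b.has_bn for b in make_variant("No-BN").blocks)

    def test_pool_types(self):
        p1, p2 = make_variant("Proposed-1"), make_variant("Proposed-2")
        assert [b.pool for b in p1.blocks] == ["max"] * 9 + ["none"]
        assert [b.pool for b in p2.blocks] == ["average"] * 9 + ["none"]
        assert make_variant("Extra-Average").pre_flatten_pool == "average"
        assert make_variant("Maxpooling").pre_flatten_pool == "max"

    def test_pool_type_never_changes_counts(self):
        assert count_trainable(make_variant("Proposed-1")) == \
            count_trainable(make_variant("Proposed-2"))

    def test_pre_flatten_pool_halves_dense_input(self):
        rows = compute_layer_summaries(make_variant("Extra-Average"))
        flat = next(r for r in rows if r.layer_kind == "flatten")
        assert flat.output_len == 2048  # vs 4608 without the extra pool

    def test_dropout_positions(self):
        spec = make_variant("Proposed-1")
        assert [i for i, b in enumerate(spec.blocks, 1) if b.dropout_after] == [6, 8, 9]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            make_variant("Proposed-3")

    def test_spec_serialization_round_trip(self):
        spec = make_variant("Extra-Average", kernel=3, n_conv_layers=9)
        from afdetect1d import ArchitectureSpec
        assert ArchitectureSpec.from_dict(spec.to_dict()) == spec


class TestFeasibility:
    @pytest.mark.parametrize("layers,kernel,expected", [
        (11, 5, False), (11, 7, False),  # the N/A corners
        (11, 3, True), (10, 7, True), (10, 5, True), (8, 3, True),
    ])
    def test_known_cells(self, layers, kernel, expected):
        assert check_feasible(layers, kernel, 9000) is expected

    def test_error_names_failing_layer(self):
        spec = make_variant("Proposed-1", kernel=5, n_conv_layers=11)
        with pytest.raises(FeasibilityError, match="block 11"):
            compute_layer_summaries(spec)

    def test_build_rejects_infeasible(self):
        with pytest.raises(FeasibilityError):
            build_network(make_variant("Proposed-1", kernel=7, n_conv_layers=11))


class TestBuilder:
    def test_built_count_matches_analytic_small(self):
        spec = make_variant("All-BN", kernel=3, n_conv_layers=8, input_len=700)
        assert build_network(spec, seed=0).n_trainable() == count_trainable(spec)

    def test_forward_outputs_softmaxable_logits(self):
        from afdetect1d import nn
        spec = make_variant("Proposed-2", kernel=3, n_conv_layers=8, input_len=700)
        net = build_network(spec, seed=0)
        x = np.random.default_rng(0).normal(size=(3, 700)).astype(np.float32)
        probs = nn.softmax(net.forward(x))
        assert probs.shape == (3, 4)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_seeded_build_is_deterministic(self):
        spec = make_variant("Proposed-1", kernel=3, n_conv_layers=8, input_len=700)
        x = np.random.default_rng(1).normal(size=(2, 700)).astype(np.float32)
        out1 = build_network(spec, seed=5).forward(x)
        out2 = build_network(spec, seed=5).forward(x)
        np.testing.assert_array_equal(out1, out2)

    def test_describe_prints_totals(self):
        text = describe(make_variant("Proposed-1"))
        assert "3,212,740" in text and "3,212,804" in text


def test_all_variants_buildable_at_reduced_length():
    # 1000 samples keeps even the pre-flatten-pool variants feasible at 8 blocks
    for name in VARIANT_NAMES:
        spec = make_variant(name, kernel=3, n_conv_layers=8, input_len=1000)
        assert build_network(spec, seed=0).n_trainable() == count_trainable(spec)
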