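"""Architecture spec, analytic shape trace, built network, parameters."""

import numpy as np
import pytest

from nucseg.model import (DOWN_CONV1, DOWN_CONV2, MIDDLE_CONV, UP_CONV1,
                          UP_CONV2, SpecError, build_network, count_parameters,
                          default_spec, shape_trace)

# the full layer table: (layer, height, width, channels)
LAYER_TABLE = [
    ("downblock-1/conv1", 128, 128, 8), ("downblock-1/conv2", 128, 128, 8),
    ("downblock-2/conv1", 64, 64, 16), ("downblock-2/conv2", 64, 64, 16),
    ("downblock-3/conv1", 32, 32, 32), ("downblock-3/conv2", 32, 32, 32),
    ("downblock-4/conv1", 16, 16, 64), ("downblock-4/conv2", 16, 16, 64),
    ("downblock-5/conv1", 8, 8, 128), ("downblock-5/conv2", 8, 8, 16),
    ("downblock-6/conv1", 4, 4, 256), ("downblock-6/conv2", 4, 4, 32),
    ("middleblock/conv1", 2, 2, 512), ("middleblock/conv2", 2, 2, 64),
    ("upblock-6/conv1", 4, 4, 256), ("upblock-6/conv2", 4, 4, 32),
    ("upblock-5/conv1", 8, 8, 128), ("upblock-5/conv2", 8, 8, 16),
    ("upblock-4/conv1", 16, 16, 64), ("upblock-4/conv2", 16, 16, 64),
    ("upblock-3/conv1", 32, 32, 32), ("upblock-3/conv2", 32, 32, 32),
    ("upblock-2/conv1", 64, 64, 16), ("upblock-2/conv2", 64, 64, 16),
    ("upblock-1/conv1", 128, 128, 8), ("upblock-1/conv2", 128, 128, 8),
]


def spec_parameter_count(spec):
    """Closed-form oracle: sum kh*kw*cin*cout + cout over every conv,
    derived purely from the declarative spec (independent of the
    built model's bookkeeping)."""
    total = 0
    c = spec.input_shape[2]
    skip = {}
    for b in spec.down_blocks() + [spec.middle_block()]:
        total += 9 * c * b.conv1_filters + b.conv1_filters
        total += 9 * b.conv1_filters * b.conv2_filters + b.conv2_filters
        c = b.conv2_filters
        if b.kind == "down":
            skip[b.name] = c
    for b in spec.up_blocks():
        total += 4 * c * b.conv1_filters + b.conv1_filters       # 2x2 tconv
        cin = b.conv1_filters + skip[b.skip_partner]
        total += 9 * cin * b.conv1_filters + b.conv1_filters
        total += 9 * b.conv1_filters * b.conv2_filters + b.conv2_filters
        c = b.conv2_filters
    total += 1 * c * spec.output_classes + spec.output_classes   # 1x1 head
    return total


class TestSpec:
    def test_default_schedule_matches_layer_table(self):
        spec = default_spec()
        downs = spec.down_blocks()
        assert tuple(b.conv1_filters for b in downs) == DOWN_CONV1
        assert tuple(b.conv2_filters for b in downs) == DOWN_CONV2
        mb = spec.middle_block()
        assert (mb.conv1_filters, mb.conv2_filters) == MIDDLE_CONV == (512, 64)
        ups = spec.up_blocks()
        assert tuple(b.conv1_filters for b in ups) == UP_CONV1
        assert tuple(b.conv2_filters for b in ups) == UP_CONV2
        out = spec.blocks[-1]
        assert out.activation == "softmax" and spec.output_classes == 2

    def test_structural_invariants_enforced(self):
        spec = default_spec()
        spec.blocks[0].pool_before = True  # downblock-1 must not pool
        with pytest.raises(SpecError, match="downblock-1"):
            spec.validate()

    def test_bad_skip_partner_rejected(self):
        spec = default_spec()
        spec.up_blocks()[0].skip_partner = "nonexistent"
        with pytest.raises(SpecError, match="upblock-6"):
            spec.validate()

    def test_yaml_round_trip(self, tmp_path):
        spec = default_spec(width_divisor=4)
        spec.to_yaml(tmp_path / "spec.yaml")
        from nucseg.model import NetworkSpec
        loaded = NetworkSpec.from_yaml(tmp_path / "spec.yaml")
        assert loaded == spec


class TestShapeTrace:
    def test_full_trace_matches_layer_table(self):
        trace = shape_trace(default_spec())
        for name, h, w, c in LAYER_TABLE:
            assert trace.shape(name) == (h, w, c), name
        assert trace.shape("input") == (128, 128, 3)
        assert trace.shape("output") == (128, 128, 2)

    def test_up_down_spatial_symmetry(self):
        trace = shape_trace(default_spec())
        for i in range(1, 7):
            dh, dw, _ = trace.shape(f"downblock-{i}/conv2")
            uh, uw, _ = trace.shape(f"upblock-{i}/conv2")
            assert (dh, dw) == (uh, uw)

    def test_trace_exports_table_shaped_frame(self):
        df = shape_trace(default_spec()).to_frame()
        assert list(df.columns) == ["layer", "height", "width", "channels"]
        assert len(df) == len(LAYER_TABLE) + 2 + 6 * 2  # + input/output + up aux rows


@pytest.fixture(scope="module")
def small_model():
    return build_network(default_spec(width_divisor=8), seed=3)


class TestBuiltNetwork:
    def test_softmax_channels_sum_to_one(self, small_model):
        x = np.zeros((1, 64, 64, 3), dtype=np.float32)
        probs = small_model.forward(x)
        assert probs.shape == (1, 64, 64, 2)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_same_seed_same_outputs(self):
        rng = np.random.default_rng(0)
        x = rng.random((1, 64, 64, 3)).astype(np.float32)
        m1 = build_network(default_spec(width_divisor=8), seed=11)
        m2 = build_network(default_spec(width_divisor=8), seed=11)
        np.testing.assert_array_equal(m1.forward(x), m2.forward(x))

    def test_full_model_forward_shape(self):
        model = build_network(default_spec(), seed=1)
        x = np.random.default_rng(2).random((1, 128, 128, 3)).astype(np.float32)
        assert model.forward(x).shape == (1, 128, 128, 2)

    def test_parameter_count_matches_closed_form(self):
        for div in (1, 8):
            spec = default_spec(width_divisor=div)
            model = build_network(spec, seed=0)
            total, per_block = count_parameters(model)
            assert total == spec_parameter_count(spec)
            assert sum(per_block.values()) == total
            assert all(v > 0 for v in per_block.values())

    def test_single_conv_parameter_count(self):
        from nucseg.nn.layers import Conv2D
        conv = Conv2D(3, 8, 3, np.random.default_rng(0))
        assert sum(a.size for a in conv.params.values()) == 3 * 3 * 3 * 8 + 8

    def test_skip_ablation_changes_output(self, small_model):
        x = np.random.default_rng(4).random((1, 64, 64, 3)).astype(np.float32)
        baseline = small_model.forward(x)
        originals = {}
        for blk in small_model.up:
            w = blk["conv1"].params["W"]
            nc, cin = blk["tconv"].c_out, blk["conv1"].c_in
            originals[blk["name"]] = w.copy()
            # rows are flattened (kh, kw, channel); channels >= nc are the skip
            skip_rows = [r for r in range(w.shape[0]) if r % cin >= nc]
            w[skip_rows, :] = 0.0
        ablated = small_model.forward(x)
        for blk in small_model.up:
            blk["conv1"].params["W"][...] = originals[blk["name"]]
        assert not np.allclose(baseline, ablated)

    def test_constant_input_gives_constant_interior_activations(self):
        # 'same' zero padding only perturbs a 1-pixel border per 3x3 conv
        from nucseg.nn.layers import Conv2D
        conv = Conv2D(3, 4, 3, np.random.default_rng(5))
        x = np.full((1, 16, 16, 3), 0.7, dtype=np.float32)
        y = conv.forward(x)
        interior = y[0, 1:-1, 1:-1, :]
        np.testing.assert_allclose(
            np.broadcast_to(interior[0, 0], interior.shape), interior,
            rtol=1e-5, atol=1e-6)

    def test_checkpoint_round_trip(self, tmp_path, small_model):
        x = np.random.default_rng(6).random((1, 64, 64, 3)).astype(np.float32)
        before = small_model.forward(x)
        path = tmp_path / "w.npz"
        small_model.save_weights(path)
        other = build_network(default_spec(width_divisor=8), seed=999)
        assert not np.allclose(other.forward(x), before)
        other.load_weights(path)
        np.testing.assert_array_equal(other.forward(x), before)
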