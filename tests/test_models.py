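import numpy as np
import pytest

import eitgest as eg
from eitgest.models import PRESETS, TrainConfig, preset, prepare_inputs


class TestPresets:
    def test_table_grid_row_late_fusion(self):
        spec = preset("CNN 3 L D-25")
        assert (spec.filters_1, spec.filters_2) == (64, 64)
        assert (spec.dropout_1, spec.dropout_2) == (0.25, 0.25)
        assert (spec.num_convs, spec.dilation_rate) == (3, 3)
        assert spec.fusion == "late"

    def test_table_grid_row_early_fusion(self):
        spec = preset("CNN 9 E")
        assert (spec.filters_1, spec.filters_2) == (128, 128)
        assert spec.fusion == "early"
        assert (spec.num_convs, spec.dilation_rate) == (1, 2)
        assert spec.dropout_1 == spec.dropout_2 == 0.0

    def test_unreg_variants_differ_only_in_dropout(self):
        a, b = preset("MLP 1"), preset("MLP 1 Unreg")
        assert a.hidden_layers == b.hidden_layers == (128, 128)
        assert a.hidden_dropout == (0.5, 0.5)
        assert b.hidden_dropout == (0.0, 0.0)

    def test_mlp2_dropout_on_first_two_layers_only(self):
        spec = preset("MLP 2")
        assert spec.hidden_layers == (256, 128, 64)
        assert spec.hidden_dropout == (0.5, 0.5, 0.0)

    def test_cnn1_cnn2_block_structure(self):
        c1, c2 = preset("CNN 1"), preset("CNN 2")
        assert c1.filters == (64,) * 4 and c1.dilation == (1, 3, 3, 3)
        assert c1.block_dropout == (0.25,) * 4
        assert c2.filters == (64,) * 3 and c2.dilation == (1, 1, 2)
        assert c2.block_dropout == (0.0,) * 3

    def test_unknown_preset_lists_options(self):
        with pytest.raises(KeyError, match="MLP 1"):
            preset("MLP 99")

    def test_eighteen_grid_variants_ship(self):
        grid = [n for n in PRESETS if n.startswith("CNN ") and n not in ("CNN 1", "CNN 2")]
        assert len(grid) == 18


class TestBuilders:
    def test_all_presets_forward_a_simulated_frame(self, small_ds):
        refs = small_ds.values
        for name, spec in PRESETS.items():
            model = eg.build_model(spec, small_ds.schedule, seed=0)
            if spec.dual_input:
                x = prepare_inputs(spec, small_ds, refs)
                out = model.forward(tuple(a[:1] for a in x), train=False)
            else:
                out = model.forward(prepare_inputs(spec, small_ds)[:1], train=False)
            assert out.shape == (1, 12), name
            assert np.isfinite(out).all(), name

    def test_same_spec_same_count_different_weights_across_seeds(self, schedule16):
        spec = preset("MLP 1")
        m1 = eg.build_model(spec, schedule16, seed=0)
        m2 = eg.build_model(spec, schedule16, seed=1)
        assert m1.n_params() == m2.n_params()
        assert not np.array_equal(m1.params()[0][0], m2.params()[0][0])

    def test_late_fusion_adds_exactly_one_branch_copy(self, schedule16):
        """CNN 4 L and CNN 8 E share all grid parameters and differ only in
        fusion; the late variant carries one extra pre-fusion branch."""
        early = eg.build_model(preset("CNN 8 E"), schedule16)
        late = eg.build_model(preset("CNN 4 L"), schedule16)
        branch = late.branch_a.params()
        branch_params = sum(v.size for v, _ in branch)
        # early fusion's single stage reads 2 channels instead of 1: its first
        # conv kernel is wider by one input channel (3*3*64 weights)
        first_conv_extra = 3 * 3 * 64
        # late fusion's post-fusion conv reads 128 channels instead of 64
        post_conv_extra = 3 * 3 * 64 * 64
        assert late.n_params() - early.n_params() == (
            branch_params - first_conv_extra + post_conv_extra)

    def test_dual_mlp4_structure(self, schedule16):
        model = eg.build_model(preset("MLP 4 dual"), schedule16)
        # two independent copies of the 256-128-64 stack
        assert model.branch_a.n_params() == model.branch_b.n_params()
        wa = model.branch_a.params()[0][0]
        wb = model.branch_b.params()[0][0]
        assert wa.shape == (208, 256)
        assert not np.array_equal(wa, wb)  # no weight sharing
        # head is the classifier on the concatenated 128-dim embedding
        assert model.head.params()[0][0].shape == (128, 12)

    def test_early_fusion_mlp_takes_concatenated_input(self, schedule16):
        model = eg.build_model(preset("MLP 3"), schedule16)
        assert model.head.params()[0][0].shape == (416, 128)  # 2 x 208 fused


class TestTraining:
    def test_one_class_training_predicts_that_class(self, small_ds):
        spec = preset("MLP 1 Unreg")
        tr = small_ds.select(gesture=0, session="1")
        te = small_ds.select(session="2", iteration=1)
        model = eg.build_model(spec, small_ds.schedule, seed=0)
        res = eg.train(model, tr.values, tr.labels, te.values, te.labels,
                       TrainConfig(epochs=5, batch_size=8, seed=0))
        freq = (te.labels == 0).mean()
        assert res.best_test_accuracy == pytest.approx(freq)

    def test_label_permutation_trains_to_chance(self, small_ds):
        """Shuffling labels destroys the class signal; best test accuracy
        must stay near the 1/12 chance level (leakage sanity check)."""
        spec = preset("MLP 1 Unreg")
        sess = small_ds.select(session="1")
        rng = np.random.default_rng(0)
        y = rng.permutation(sess.labels)
        split = rng.random(len(y)) < 0.75
        model = eg.build_model(spec, small_ds.schedule, seed=0)
        res = eg.train(model, sess.values[split], y[split],
                       sess.values[~split], y[~split],
                       TrainConfig(epochs=10, batch_size=16, seed=0))
        assert res.best_test_accuracy < 3 / 12

    def test_result_curves_and_best(self, small_ds):
        spec = preset("MLP 1 Unreg")
        tr = small_ds.select(session="1", iteration=[1, 2])
        te = small_ds.select(session="1", iteration=3)
        model = eg.build_model(spec, small_ds.schedule, seed=1)
        res = eg.train(model, tr.values, tr.labels, te.values, te.labels,
                       TrainConfig(epochs=4, batch_size=32, seed=1))
        assert len(res.test_accuracy) == len(res.test_loss) == 4
        assert res.best_test_accuracy == max(res.test_accuracy)

    def test_fixed_seed_reproduces_trajectory(self, small_ds):
        spec = preset("MLP 2")
        tr = small_ds.select(session="1", iteration=[1, 2])
        te = small_ds.select(session="1", iteration=3)
        curves = []
        for _ in range(2):
            model = eg.build_model(spec, small_ds.schedule, seed=3)
            res = eg.train(model, tr.values, tr.labels, te.values, te.labels,
                           TrainConfig(epochs=3, batch_size=16, seed=3))
            curves.append(res.test_accuracy)
        assert curves[0] == curves[1]

    def test_empty_split_rejected(self, small_ds, schedule16):
        spec = preset("MLP 1")
        model = eg.build_model(spec, schedule16)
        with pytest.raises(ValueError, match="non-empty"):
            eg.train(model, np.empty((0, 208)), np.empty(0, dtype=int),
                     small_ds.values, small_ds.labels, TrainConfig(epochs=1))


def test_svm_hook_returns_standard_classifier():
    clf = eg.models.svm_baseline("poly", degree=2)
    assert clf.kernel == "poly" and clf.degree == 2
    with pytest.raises(ValueError):
        eg.models.svm_baseline("sigmoid")
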