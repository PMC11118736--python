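"""ConvGRU recurrence, class weights, mean distance and subset balancing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungfat import autodiff as ad
from lungfat.imaging_io import CTSlice, LocalizationLabel, SliceWindow
from lungfat.localizer import (
    ConvBiGRUClassifier,
    ConvGRUParams,
    LocalizerConfig,
    balance_subsets,
    bigru_forward,
    classify_window,
    compute_class_weights,
    gru_cell_step,
    mean_distance,
)


def _random_params(seed, in_ch=1, hidden=1, k=1):
    rng = np.random.default_rng(seed)
    params = ConvGRUParams(rng, in_ch, hidden, k)
    for P in (params.W_z, params.W_r, params.W_h):
        P.data = rng.normal(size=P.data.shape)
    for Pb in (params.b_z, params.b_r, params.b_h):
        Pb.data = rng.normal(size=Pb.data.shape)
    return params


def _scalar_gru(x, h, params, literal=False):
    """Per-pixel scalar reference of the gated recurrence (1x1 kernels).

    Channel 0 of each kernel weights the hidden state, channel 1 the
    input, matching the [h_prev, x] concatenation order.
    """
    wz = params.W_z.data[0, :, 0, 0]
    wr = params.W_r.data[0, :, 0, 0]
    wh = params.W_h.data[0, :, 0, 0]
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    z = sig(wz[0] * h + wz[1] * x + params.b_z.data[0])
    r = sig(wr[0] * h + wr[1] * x + params.b_r.data[0])
    pre = wh[0] * (r * h) + wh[1] * x + params.b_h.data[0]
    cand = math.tanh(sig(pre)) if literal else math.tanh(pre)
    return (1 - z) * h + z * cand


class TestGRUCell:
    def test_zero_kernels_halve_previous_hidden(self, rng):
        params = ConvGRUParams(np.random.default_rng(0), 1, 1, 3)
        for P in (params.W_z, params.W_r, params.W_h):
            P.data[...] = 0.0
        h_prev = rng.normal(size=(1, 1, 4, 4))
        out = gru_cell_step(ad.Tensor(np.zeros((1, 1, 4, 4))), ad.Tensor(h_prev), params)
        np.testing.assert_allclose(out.data, 0.5 * h_prev, atol=1e-12)

    def test_saturated_update_gate_returns_candidate(self, rng):
        params = _random_params(3)
        params.b_z.data[...] = 50.0  # drives z -> 1
        x = rng.normal(size=(1, 1, 3, 3))
        h = rng.normal(size=(1, 1, 3, 3))
        out = gru_cell_step(ad.Tensor(x), ad.Tensor(h), params).data
        expect = np.array(
            [
                [
                    _scalar_gru(x[0, 0, i, j], h[0, 0, i, j], params)
                    for j in range(3)
                ]
                for i in range(3)
            ]
        )
        np.testing.assert_allclose(out[0, 0], expect, atol=1e-6)

    @pytest.mark.parametrize("literal", [False, True])
    def test_matches_scalar_oracle_on_random_instances(self, literal):
        for trial in range(20):
            params = _random_params(trial)
            r = np.random.default_rng(1000 + trial)
            x = r.normal(size=(1, 1, 2, 2))
            h = r.normal(size=(1, 1, 2, 2))
            out = gru_cell_step(
                ad.Tensor(x), ad.Tensor(h), params, literal_candidate=literal
            ).data
            for i in range(2):
                for j in range(2):
                    expect = _scalar_gru(
                        x[0, 0, i, j], h[0, 0, i, j], params, literal
                    )
                    assert out[0, 0, i, j] == pytest.approx(expect, abs=1e-6)

    def test_output_between_hidden_and_candidate(self, rng):
        # h_t = (1-z) h + z h~ is a convex combination elementwise
        params = _random_params(9, hidden=2, k=3)
        x = ad.Tensor(rng.normal(size=(2, 1, 6, 6)))
        h_prev = ad.Tensor(rng.normal(size=(2, 2, 6, 6)))
        cat = ad.concat([h_prev, x], axis=1)
        r = ad.sigmoid(ad.conv2d(cat, params.W_r, params.b_r))
        cand = ad.tanh(
            ad.conv2d(ad.concat([ad.mul(r, h_prev), x], axis=1), params.W_h, params.b_h)
        )
        out = gru_cell_step(x, h_prev, params).data
        lo = np.minimum(h_prev.data, cand.data)
        hi = np.maximum(h_prev.data, cand.data)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_shape_mismatch_rejected(self, rng):
        params = _random_params(0)
        with pytest.raises(ValueError, match="spatial dims"):
            gru_cell_step(
                ad.Tensor(rng.normal(size=(1, 1, 4, 4))),
                ad.Tensor(rng.normal(size=(1, 1, 3, 3))),
                params,
            )


class TestBiGRU:
    def test_identical_slices_shared_params_give_symmetric_halves(self, rng):
        params = _random_params(4, hidden=2, k=3)
        x = rng.normal(size=(1, 1, 5, 5))
        out = bigru_forward([ad.Tensor(x)] * 5, params, params).data
        np.testing.assert_allclose(out[:, :2], out[:, 2:], atol=1e-12)

    def test_single_step_directions_agree(self, rng):
        params = _random_params(5, hidden=2, k=3)
        x = rng.normal(size=(1, 1, 4, 4))
        out = bigru_forward([ad.Tensor(x)], params, params).data
        np.testing.assert_allclose(out[:, :2], out[:, 2:], atol=1e-12)

    def test_three_step_matches_unrolled_recurrence(self):
        fwd = _random_params(6)
        bwd = _random_params(7)
        r = np.random.default_rng(8)
        xs = [r.normal(size=(1, 1, 2, 2)) for _ in range(3)]
        out = bigru_forward([ad.Tensor(x) for x in xs], fwd, bwd).data
        for i in range(2):
            for j in range(2):
                hf = 0.0
                for x in xs:
                    hf = _scalar_gru(x[0, 0, i, j], hf, fwd)
                hb = 0.0
                for x in xs[::-1]:
                    hb = _scalar_gru(x[0, 0, i, j], hb, bwd)
                assert out[0, 0, i, j] == pytest.approx(hf, abs=1e-6)
                assert out[0, 1, i, j] == pytest.approx(hb, abs=1e-6)

    def test_empty_window_rejected(self):
        p = _random_params(0)
        with pytest.raises(ValueError, match="empty"):
            bigru_forward([], p, p)


class TestClassifier:
    def _window(self, rng, L=5):
        slices = [
            CTSlice(pixels=rng.integers(0, 4096, size=(32, 32)), spacing_mm=2.5, index=i)
            for i in range(L)
        ]
        return SliceWindow(slices=slices, label=LocalizationLabel.OTHER)

    def test_probabilities_sum_to_one(self, rng):
        model = ConvBiGRUClassifier(LocalizerConfig(hidden_channels=2, seed=0))
        probs = classify_window(self._window(rng), model)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(probs > 0) and np.all(probs < 1)

    def test_zeroed_head_gives_uniform_prediction(self, rng):
        model = ConvBiGRUClassifier(LocalizerConfig(hidden_channels=2, seed=0))
        model.head.weight.data[...] = 0.0
        model.head.bias.data[...] = 0.0
        probs = classify_window(self._window(rng), model)
        np.testing.assert_allclose(probs, [1 / 3] * 3, atol=1e-12)

    def test_wrong_window_length_rejected(self, rng):
        model = ConvBiGRUClassifier(LocalizerConfig(window_length=5, hidden_channels=2))
        with pytest.raises(ValueError, match="window length"):
            model.logits(rng.normal(size=(1, 3, 16, 16)))


class TestTrainingConvergence:
    def test_classifier_learns_200_balanced_phantom_windows(self):
        """Trained on 200 prevalence-balanced windows (the subset-balancing
        regime), the ConvBiGRU separates FIRST/OTHER/LAST at >= 0.9
        training accuracy."""
        from lungfat.phantom import generate_cohort
        from lungfat.pipeline import _volume_windows
        from lungfat.localizer import train_localizer, training_accuracy

        vols = generate_cohort(50, image_size=32, seed=100)
        wins = _volume_windows(vols, 5)
        rng = np.random.default_rng(0)
        first = [w for w in wins if w.label == LocalizationLabel.FIRST]
        last = [w for w in wins if w.label == LocalizationLabel.LAST]
        other = [w for w in wins if w.label == LocalizationLabel.OTHER]
        train = first[:50] + last[:50] + [
            other[i] for i in rng.permutation(len(other))[:100]
        ]
        assert len(train) == 200
        cfg = LocalizerConfig(
            window_length=5, hidden_channels=8, kernel_size=3, seed=1,
            batch_size=25,
        )
        model = ConvBiGRUClassifier(cfg)
        train_localizer(model, train, epochs=30, lr=1.0, seed=2)
        train_localizer(model, train, epochs=12, lr=0.2, seed=3)
        assert training_accuracy(model, train) >= 0.9


class TestClassWeights:
    def test_single_class_weight_is_inverse_log_two_point_one(self):
        cw = compute_class_weights([17])
        assert cw.normalized[0] == 1.0
        assert cw.W[0] == pytest.approx(1.0 / math.log(2.1))

    def test_two_equal_classes(self):
        cw = compute_class_weights([1, 1])
        np.testing.assert_allclose(cw.W, 1.0 / math.log(1.6))
        assert cw.W[0] == pytest.approx(2.1276, abs=1e-4)

    def test_rarest_class_gets_largest_weight(self):
        cw = compute_class_weights([320, 320, 60])
        assert np.argmax(cw.W) == 2

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_class_weights([3, 0, 2])
        with pytest.raises(ValueError, match="alpha"):
            compute_class_weights([1, 2], alpha=1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(1, 10_000), min_size=2, max_size=6))
    def test_weights_inside_stated_open_interval(self, counts):
        # with >= 2 classes every fraction is in (0, 1), so W is strictly
        # interior; the one-class case sits exactly on the lower endpoint
        cw = compute_class_weights(counts, alpha=1.1)
        lo, hi = 1.0 / math.log(2.1), 1.0 / math.log(1.1)
        assert np.all(cw.W > lo) and np.all(cw.W < hi)
        assert cw.normalized.sum() == pytest.approx(1.0, abs=1e-9)


class TestMeanDistance:
    def test_single_volume_distance(self):
        assert mean_distance([10], [8], [2.5]) == pytest.approx(5.0)

    def test_exact_predictions_give_zero(self):
        assert mean_distance([3, 7], [3, 7], [2, 5]) == 0.0

    def test_worked_two_volume_example(self):
        assert mean_distance([3, 7], [1, 7], [2, 5]) == pytest.approx(2.0)

    def test_absolute_value_keeps_distance_non_negative(self):
        assert mean_distance([1], [9], [1.0]) == pytest.approx(8.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            mean_distance([1, 2], [1], [1.0, 1.0])


class TestBalanceSubsets:
    def _windows(self, n_pos, n_neg, rng):
        out = []
        for i in range(n_pos + n_neg):
            lab = (
                LocalizationLabel.FIRST if i < n_pos else LocalizationLabel.OTHER
            )
            slices = [
                CTSlice(pixels=np.zeros((8, 8), dtype=int) + 1 + j,
                        spacing_mm=1.0, index=j)
                for j in range(3)
            ]
            out.append(SliceWindow(slices=slices, label=lab))
        return out

    def test_exact_positive_counts(self, rng):
        ds = self._windows(60, 90, rng)
        subsets = balance_subsets(ds, 3, 20, tolerance=0, seed=1)
        for sub in subsets:
            n_pos = sum(w.label != LocalizationLabel.OTHER for w in sub)
            assert n_pos == 20

    def test_subsets_disjoint(self, rng):
        ds = self._windows(30, 60, rng)
        subsets = balance_subsets(ds, 3, 10, seed=2)
        ids = [id(w) for sub in subsets for w in sub]
        assert len(ids) == len(set(ids))

    def test_infeasible_target_reports_counts(self, rng):
        ds = self._windows(10, 30, rng)
        with pytest.raises(ValueError, match="10 positive"):
            balance_subsets(ds, 3, 20, seed=0)

    def test_seeded_determinism(self, rng):
        ds = self._windows(30, 60, rng)
        a = balance_subsets(ds, 3, 10, seed=7)
        b = balance_subsets(ds, 3, 10, seed=7)
        assert [[id(w) for w in s] for s in a] == [[id(w) for w in s] for s in b]
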