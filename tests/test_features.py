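"""Band filtering, differential entropy, and the symmetric feature matrices."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from symaxion.features import (
    DEFAULT_BANDS,
    BandSpec,
    EpochSet,
    bandpass,
    de_stack,
    differential_entropy,
    normalize,
    oef_stack,
    qsm_stack,
    ssm_stack,
    symmetric_quotient,
    symmetric_subtract,
)
from symaxion.montage import symmetric_pairs, vector_to_grid

ALPHA = DEFAULT_BANDS[2]
GAMMA = DEFAULT_BANDS[4]


def _sine_epochs(freq, n_channels=62, fs=200.0, amplitude=1.0):
    t = np.arange(200) / fs
    data = amplitude * np.sin(2 * np.pi * freq * t)[None, None, :] * np.ones((1, n_channels, 1))
    return EpochSet(data, fs, [0], ("only",))


class TestBandpass:
    def test_passband_preserves_amplitude(self):
        out = bandpass(_sine_epochs(10.0), ALPHA)
        # compare RMS in the central part, away from filter edges
        seg = slice(50, 150)
        ratio = out.data[0, 0, seg].std() / _sine_epochs(10.0).data[0, 0, seg].std()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_attenuates(self):
        out = bandpass(_sine_epochs(10.0), GAMMA)
        assert out.data.std() < 0.1 * _sine_epochs(10.0).data.std()

    def test_dc_removed(self):
        epochs = EpochSet(np.full((1, 62, 200), 7.0), 200.0, [0], ("only",))
        for band in DEFAULT_BANDS:
            assert np.abs(bandpass(epochs, band).data).max() < 1e-6

    def test_band_above_nyquist_rejected(self):
        epochs = _sine_epochs(10.0)
        with pytest.raises(ValueError):
            bandpass(epochs, BandSpec("too_high", 90.0, 120.0))

    def test_invalid_band_edges_rejected(self):
        with pytest.raises(ValueError):
            BandSpec("bad", 12.0, 8.0)


class TestDifferentialEntropy:
    def test_closed_form_zero(self, rng):
        x = rng.standard_normal(200)
        x = (x - x.mean()) / x.std() / np.sqrt(2 * np.pi * np.e)  # var = 1/(2*pi*e)
        assert abs(differential_entropy(x)) < 1e-9

    def test_closed_form_unit_variance(self, rng):
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std()
        expected = 0.5 * np.log(2 * np.pi * np.e)
        assert abs(differential_entropy(x) - expected) < 1e-9
        assert abs(expected - 1.41894) < 1e-5

    @given(st.floats(0.01, 100.0))
    def test_scale_law(self, c):
        x = np.random.default_rng(3).standard_normal(200)
        assert abs(differential_entropy(c * x) - differential_entropy(x) - np.log(c)) < 1e-9

    def test_zero_variance_floored_with_warning(self):
        with pytest.warns(RuntimeWarning):
            val = differential_entropy(np.zeros(200))
        assert np.isfinite(val)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            differential_entropy(np.ones(1))


class TestStacks:
    def test_de_stack_depth_is_band_count(self, small_epochs, layout):
        stack = de_stack(small_epochs, DEFAULT_BANDS, layout)
        assert stack.maps.shape == (small_epochs.n_epochs, 5, 9, 9)
        assert stack.band_names == ("delta", "theta", "alpha", "beta", "gamma")

    def test_de_stack_zero_outside_occupied_cells(self, small_epochs, layout):
        stack = de_stack(small_epochs, DEFAULT_BANDS, layout)
        assert (stack.maps[..., ~layout.occupancy] == 0).all()

    def test_white_noise_gives_flat_alpha_grid(self, white_noise_epochs, layout):
        """Equal-variance white noise puts (near-)equal band power everywhere."""
        stack = de_stack(white_noise_epochs, DEFAULT_BANDS, layout)
        alpha = stack.maps[:, 2][..., layout.occupancy]  # epochs x channels
        # a 4-Hz band of a 1-s window has ~2*BW*T = 8 dof, so the DE of one
        # window scatters with sd ~ sqrt(2/8) = 0.5; averaging 16 epochs
        # leaves ~0.125 channel-to-channel spread if there is no structure
        spread = alpha.mean(axis=0).std()
        assert spread < 0.25

    def test_oef_stack_depth_equals_samples(self, small_epochs, layout):
        stack = oef_stack(small_epochs, layout)
        assert stack.maps.shape == (small_epochs.n_epochs, 200, 9, 9)

    def test_oef_constant_epoch_gives_ones_grids(self, layout):
        epochs = EpochSet(np.ones((1, 62, 200)), 200.0, [0], ("only",))
        stack = oef_stack(epochs, layout)
        expected = vector_to_grid(np.ones(62), layout)
        assert np.array_equal(stack.maps[0, 0], expected)
        assert np.array_equal(stack.maps[0, 123], expected)

    def test_oef_rejects_non_one_second_epochs(self, layout, rng):
        epochs = EpochSet(rng.standard_normal((2, 62, 150)), 200.0, [0, 0], ("x",))
        with pytest.raises(ValueError, match="1-s"):
            oef_stack(epochs, layout)

    def test_oef_slice_matches_gridded_sample(self, small_epochs, layout):
        stack = oef_stack(small_epochs, layout)
        t = 17
        expected = vector_to_grid(small_epochs.data[0, :, t], layout)
        assert np.array_equal(stack.maps[0, t], expected)


class TestSymmetricVectors:
    def test_mirror_equal_halves_subtract_to_zero(self, rng):
        half = rng.standard_normal(27)
        assert np.allclose(symmetric_subtract(np.concatenate([half, half])), 0)

    def test_antisymmetry(self, rng):
        v = rng.standard_normal(54)
        d = symmetric_subtract(v)
        assert np.allclose(d[27:], -d[:27])

    def test_subtract_against_pair_loop(self):
        v = np.concatenate([np.arange(1.0, 28.0), np.zeros(27)])
        d = symmetric_subtract(v)
        expected = np.concatenate([np.arange(1.0, 28.0), -np.arange(1.0, 28.0)])
        assert np.array_equal(d, expected)

    def test_mirror_equal_halves_quotient_to_one(self, rng):
        half = rng.standard_normal(27) + 3.0
        assert np.allclose(symmetric_quotient(np.concatenate([half, half])), 1)

    def test_reciprocal_property(self, rng):
        v = rng.uniform(0.5, 2.0, 54)
        q = symmetric_quotient(v)
        assert np.allclose(q[:27] * q[27:], 1)

    def test_one_pair_toy(self):
        assert np.allclose(symmetric_quotient(np.array([2.0, 1.0])), [2.0, 0.5])

    def test_quotient_guard_never_crashes(self):
        v = np.zeros(54)
        v[:27] = 1.0
        q = symmetric_quotient(v)
        assert np.all(np.isfinite(q))
        assert q[0] == 1.0 / 1e-6  # clamped denominator

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            symmetric_subtract(np.ones(53))


def _pair_loop_oracle(grids, layout, op):
    """Independent dictionary-based per-pair implementation of SSM/QSM."""
    out = np.zeros_like(grids)
    for left, right in symmetric_pairs(layout):
        lcell, rcell = layout.grid_cell[left], layout.grid_cell[right]
        lv, rv = grids[..., lcell[0], lcell[1]], grids[..., rcell[0], rcell[1]]
        if op == "subtract":
            out[..., lcell[0], lcell[1]] = lv - rv
            out[..., rcell[0], rcell[1]] = rv - lv
        else:
            guard = lambda x: np.where(np.abs(x) < 1e-6, np.where(x < 0, -1e-6, 1e-6), x)
            out[..., lcell[0], lcell[1]] = lv / guard(rv)
            out[..., rcell[0], rcell[1]] = rv / guard(lv)
    return out


class TestSymmetricStacks:
    def test_symmetric_head_gives_zero_ssm(self, layout):
        """Mirror-symmetric scalp values subtract to an all-zero SSM."""
        vec = np.zeros(62)
        k = layout.n_pairs
        vals = np.arange(1.0, 28.0)
        vec[list(layout.lateral_order[:k])] = vals
        vec[list(layout.lateral_order[k:])] = vals
        stack = de_stack(
            EpochSet(np.random.default_rng(0).standard_normal((1, 62, 200)), 200.0, [0], ("x",)),
            DEFAULT_BANDS, layout,
        )
        stack.maps[:] = vector_to_grid(vec, layout)
        assert np.allclose(ssm_stack(stack).maps, 0)
        qsm = qsm_stack(stack).maps
        assert np.allclose(qsm[..., layout.lateral_mask], 1)
        assert np.allclose(qsm[..., ~layout.lateral_mask], 0)

    def test_depth_preserved(self, small_epochs, layout):
        de = de_stack(small_epochs, DEFAULT_BANDS, layout)
        oef = oef_stack(small_epochs, layout)
        assert ssm_stack(de).depth == 5
        assert qsm_stack(de).depth == 5
        assert ssm_stack(oef).depth == 200
        assert qsm_stack(oef).depth == 200

    def test_midline_column_zero(self, small_epochs, layout):
        de = de_stack(small_epochs, DEFAULT_BANDS, layout)
        for stack in (ssm_stack(de), qsm_stack(de)):
            midline_cells = layout.occupancy & ~layout.lateral_mask
            assert (stack.maps[..., midline_cells] == 0).all()
            assert np.count_nonzero(stack.maps[0, 0]) <= 54

    @pytest.mark.parametrize("op", ["subtract", "quotient"])
    def test_oracle_equivalence_on_random_stacks(self, layout, rng, op):
        """100 random grids match the independent per-pair lookup exactly."""
        vecs = rng.standard_normal((100, 1, 62))
        grids = vector_to_grid(vecs, layout)
        stack = de_stack(
            EpochSet(rng.standard_normal((100, 62, 200)), 200.0, np.zeros(100, int), ("x",)),
            DEFAULT_BANDS[:1], layout,
        )
        stack.maps = grids
        result = (ssm_stack(stack) if op == "subtract" else qsm_stack(stack)).maps
        expected = _pair_loop_oracle(grids, layout, op)
        # midline cells zeroed in the implementation, oracle leaves them 0 too
        assert np.array_equal(result, expected)


class TestNormalize:
    def test_three_point_slice(self, layout, small_epochs):
        stack = de_stack(small_epochs, DEFAULT_BANDS[:1], layout)
        vec = np.zeros(62)
        vec[:3] = [-2.0, 0.0, 2.0]
        stack.maps[:] = vector_to_grid(vec, layout)
        out = normalize(stack)
        cells = [stack.layout.grid_cell[i] for i in range(3)]
        vals = [out.maps[0, 0, r, c] for r, c in cells]
        assert vals == [0.0, 0.5, 1.0]
        assert out.normalized

    def test_range_and_support(self, small_epochs, layout):
        out = normalize(ssm_stack(de_stack(small_epochs, DEFAULT_BANDS, layout)))
        assert out.maps.min() >= 0 and out.maps.max() <= 1
        assert (out.maps[..., ~layout.lateral_mask] == 0).all()

    def test_idempotent_on_unit_range(self, small_epochs, layout):
        once = normalize(de_stack(small_epochs, DEFAULT_BANDS, layout))
        twice = normalize(once)
        assert np.allclose(once.maps, twice.maps)

    def test_constant_slice_maps_to_half(self, small_epochs, layout):
        stack = de_stack(small_epochs, DEFAULT_BANDS[:1], layout)
        stack.maps[:] = vector_to_grid(np.full(62, 3.3), layout)
        out = normalize(stack)
        assert (out.maps[..., layout.occupancy] == 0.5).all()
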