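"""Channel power, normalization, topomap interpolation and the ISI."""

import numpy as np
import pytest

from cogload.errors import DegenerateChannelError, ValidationError
from cogload.io import Recording
from cogload.montage import CHANNELS, electrode_positions
from cogload.topography import (
    ChannelPower,
    Topomap,
    channel_power,
    grand_average,
    image_similarity,
    normalize_recording_pair,
    render_topomap,
)


def _rec(data, condition="rest", sid="s"):
    return Recording(subject_id=sid, condition=condition, fs=100.0, data=data)


def _pair(seed=0, task_scale=1.0):
    rng = np.random.default_rng(seed)
    rest = rng.standard_normal((19, 400))
    task = task_scale * rng.standard_normal((19, 400))
    return _rec(rest), _rec(task, condition="task")


class TestNormalization:
    def test_scale_invariance(self):
        rest, task = _pair(1)
        n1 = normalize_recording_pair(rest, task)
        scaled = (_rec(7.0 * rest.data), _rec(7.0 * task.data, condition="task"))
        n2 = normalize_recording_pair(*scaled)
        np.testing.assert_allclose(n1[0].data, n2[0].data, rtol=1e-12)
        np.testing.assert_allclose(n1[1].data, n2[1].data, rtol=1e-12)

    def test_identical_conditions_unit_variance(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((19, 500))
        rest_n, task_n = normalize_recording_pair(_rec(data), _rec(data, condition="task"))
        for c in range(19):
            assert np.std(np.concatenate([rest_n.data[c], task_n.data[c]])) == pytest.approx(1.0)

    def test_power_ratio_preserved(self):
        rest, task = _pair(3, task_scale=np.sqrt(2.0))
        ratio_before = np.mean(task.data**2, axis=1) / np.mean(rest.data**2, axis=1)
        rest_n, task_n = normalize_recording_pair(rest, task)
        ratio_after = np.mean(task_n.data**2, axis=1) / np.mean(rest_n.data**2, axis=1)
        np.testing.assert_allclose(ratio_after, ratio_before, rtol=1e-6)

    def test_zero_variance_channel_rejected(self):
        rest, task = _pair(4)
        rest.data[5] = 0.0
        task.data[5] = 0.0
        with pytest.raises(DegenerateChannelError):
            normalize_recording_pair(rest, task)


class TestChannelPower:
    def test_unit_sine_power_half(self):
        t = np.arange(1000) / 100.0
        data = np.zeros((19, 1000))
        data[0] = np.sin(2 * np.pi * 5 * t)
        power = channel_power(_rec(data))
        assert power.power[0] == pytest.approx(0.5, rel=1e-3)
        assert power.power[1] == 0.0

    def test_white_noise_power_matches_variance(self):
        sigma = 3.0
        rng = np.random.default_rng(5)
        data = sigma * rng.standard_normal((19, 20_000))
        power = channel_power(_rec(data))
        se = sigma**2 * np.sqrt(2.0 / 20_000)
        assert np.all(np.abs(power.power - sigma**2) < 3 * se + 0.05)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((19, 300))
        shuffled = data[:, rng.permutation(300)]
        np.testing.assert_allclose(channel_power(_rec(data)).power,
                                   channel_power(_rec(shuffled)).power, rtol=1e-12)


class TestGrandAverage:
    def test_single_subject_identity(self):
        p = ChannelPower("a", "rest", np.arange(19, dtype=float))
        out = grand_average([p], {"a": "BAD"})
        np.testing.assert_array_equal(out[("BAD", "rest")], p.power)

    def test_two_identical_subjects(self):
        vals = np.linspace(0, 1, 19)
        ps = [ChannelPower("a", "task", vals), ChannelPower("b", "task", vals)]
        out = grand_average(ps, {"a": "GOOD", "b": "GOOD"})
        np.testing.assert_allclose(out[("GOOD", "task")], vals)

    def test_unassigned_subject_rejected(self):
        with pytest.raises(ValidationError):
            grand_average([ChannelPower("a", "rest", np.ones(19))], {})


class TestRenderTopomap:
    def test_uniform_input_constant_field(self):
        tm = render_topomap(np.full(19, 4.2))
        np.testing.assert_allclose(tm.grid.compressed(), 4.2, rtol=1e-9)

    def test_electrode_exactness(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 10, 19)
        tm = render_topomap(values)
        from scipy.interpolate import RBFInterpolator

        interp = RBFInterpolator(tm.coords, values, kernel="thin_plate_spline")
        np.testing.assert_allclose(interp(tm.coords), values, atol=1e-6)

    def test_hot_electrode_is_field_maximum(self):
        values = np.zeros(19)
        hot = CHANNELS.index("Cz")
        values[hot] = 5.0
        tm = render_topomap(values, grid_n=64)
        iy, ix = np.unravel_index(np.ma.argmax(tm.grid), tm.grid.shape)
        axis = np.linspace(-1, 1, 64)
        pos = electrode_positions()[hot]
        cell = 2.0 / 63
        assert abs(axis[ix] - pos[0]) <= 1.5 * cell
        assert abs(axis[iy] - pos[1]) <= 1.5 * cell

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            render_topomap(np.zeros(5))


def ssim_oracle(a, b, data_range):
    """Direct implementation of the uniform-window SSIM mean (independent
    of skimage): 7x7 windows, edge padding, sample covariance."""
    C1, C2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    r = 3
    pa = np.pad(a, r, mode="symmetric")
    pb = np.pad(b, r, mode="symmetric")
    n = 49
    out = np.empty_like(a, dtype=float)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            wa = pa[i:i + 7, j:j + 7].ravel()
            wb = pb[i:i + 7, j:j + 7].ravel()
            ua, ub = wa.mean(), wb.mean()
            va = ((wa - ua) ** 2).sum() / (n - 1)
            vb = ((wb - ub) ** 2).sum() / (n - 1)
            cab = ((wa - ua) * (wb - ub)).sum() / (n - 1)
            out[i, j] = ((2 * ua * ub + C1) * (2 * cab + C2)
                         / ((ua**2 + ub**2 + C1) * (va + vb + C2)))
    return out.mean()


class TestImageSimilarity:
    def _map(self, field):
        return Topomap(grid=np.ma.masked_array(field, mask=False),
                       coords=np.zeros((19, 2)), values=np.zeros(19))

    def test_reflexive(self):
        rng = np.random.default_rng(8)
        tm = render_topomap(rng.uniform(0, 5, 19))
        assert image_similarity(tm, tm) == pytest.approx(1.0)

    def test_symmetric(self):
        rng = np.random.default_rng(9)
        a = render_topomap(rng.uniform(0, 5, 19))
        b = render_topomap(rng.uniform(0, 5, 19))
        assert image_similarity(a, b) == pytest.approx(image_similarity(b, a))

    def test_checkerboard_matches_direct_ssim(self):
        base = np.full((12, 12), 2.0)
        checker = base + 0.5 * ((np.indices((12, 12)).sum(axis=0) % 2) * 2 - 1)
        a, b = self._map(base), self._map(checker)
        rng_val = max(base.max(), checker.max(), 0.0) - min(base.min(), checker.min(), 0.0)
        expected = ssim_oracle(base, checker, rng_val)
        assert image_similarity(a, b) == pytest.approx(expected, abs=1e-7)

    def test_noise_degrades_similarity_monotonically(self):
        rng = np.random.default_rng(10)
        base_vals = rng.uniform(1, 3, 19)
        base = render_topomap(base_vals)
        means = []
        for sigma in (0.05, 0.3, 1.5):
            isis = []
            for seed in range(5):
                noisy = render_topomap(
                    base_vals + sigma * np.random.default_rng(seed).standard_normal(19))
                isis.append(image_similarity(base, noisy))
            means.append(np.mean(isis))
        assert means[0] > means[1] > means[2]

    def test_shape_mismatch_rejected(self):
        a = render_topomap(np.ones(19), grid_n=32)
        b = render_topomap(np.ones(19), grid_n=64)
        with pytest.raises(ValidationError):
            image_similarity(a, b)

    def test_group_ordering_on_load_contrast(self):
        # a strongly contrasting rest/task pair is less similar than a
        # weakly contrasting one — the ordering the ISI exists to capture
        rest = np.linspace(1.0, 2.0, 19)
        strong_task = rest + np.linspace(2.0, 0.0, 19)
        weak_task = rest + 0.05 * np.linspace(1.0, 0.0, 19)
        tm_rest = render_topomap(rest)
        assert image_similarity(tm_rest, render_topomap(weak_task)) > \
               image_similarity(tm_rest, render_topomap(strong_task))
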