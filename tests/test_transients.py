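"""Beat segmentation, feature extraction, lusitropy and paired testing."""

import numpy as np
import pytest
from scipy import stats

from tncoupling.synthetic import TransientSpec, gen_paired_transients, gen_transients
from tncoupling.transients import (
    BeatFeatures,
    BeatWindow,
    TransientError,
    TransientTrace,
    beat_features,
    lusitropy,
    paired_response,
    segment_beats,
    trace_features,
)


def triangle_beat(scale=1.0, dt=0.005, l0=100.0, depth=10.0):
    """Linear rise to peak at 0.1*scale s, linear recovery to baseline at 0.5*scale s."""
    t = np.arange(-0.1, 0.65, dt) * scale
    deficit = np.zeros_like(t)
    rise = (t >= 0) & (t <= 0.1 * scale)
    deficit[rise] = depth * t[rise] / (0.1 * scale)
    fall = (t > 0.1 * scale) & (t <= 0.5 * scale)
    deficit[fall] = depth * (1 - (t[fall] - 0.1 * scale) / (0.4 * scale))
    return BeatWindow(t, l0 - deficit, onset_time_s=0.0)


class TestBeatFeatures:
    def test_triangular_beat_closed_form(self):
        """90% crossings of the triangle: rise at 0.09 s, recovery 0.36 s after peak."""
        f = beat_features(triangle_beat(), smooth=False)
        assert f.l0 == pytest.approx(100.0)
        assert f.amplitude_pct == pytest.approx(10.0)
        assert f.ttp90_s == pytest.approx(0.09, abs=1e-9)
        assert f.ttb90_s == pytest.approx(0.36, abs=1e-9)

    def test_amplitude_pct_definition(self):
        f = beat_features(triangle_beat(depth=8.0), smooth=False)
        assert f.amplitude_pct == pytest.approx(8.0)

    def test_time_rescaling_doubles_features(self):
        f1 = beat_features(triangle_beat(scale=1.0), smooth=False)
        f2 = beat_features(triangle_beat(scale=2.0), smooth=False)
        assert f2.ttp90_s == pytest.approx(2 * f1.ttp90_s, rel=1e-6)
        assert f2.ttb90_s == pytest.approx(2 * f1.ttb90_s, rel=1e-6)

    def test_offset_invariance(self):
        """Adding a length offset and shifting time changes nothing but L0."""
        w = triangle_beat()
        shifted = BeatWindow(w.time_s + 3.0, w.cell_length + 25.0, onset_time_s=3.0)
        f0 = beat_features(w, smooth=False)
        f1 = beat_features(shifted, smooth=False)
        assert f1.ttp90_s == pytest.approx(f0.ttp90_s)
        assert f1.ttb90_s == pytest.approx(f0.ttb90_s)
        assert f1.amplitude_pct == pytest.approx(f0.amplitude_pct * 100.0 / 125.0)

    def test_no_recovery_marks_missing(self):
        w = triangle_beat()
        cut = w.time_s <= 0.12   # stop right after the peak
        f = beat_features(BeatWindow(w.time_s[cut], w.cell_length[cut], 0.0), smooth=False)
        assert f.ttb90_s is None


class TestSegmentBeats:
    def test_ten_second_trace_gives_ten_windows(self):
        traces, _ = gen_transients(TransientSpec(n_cells=1, noise_sd_um=0.0, cell_cv=0.0, seed=0))
        assert len(segment_beats(traces[0])) == 10

    def test_missed_beat_warns_and_drops_window(self):
        traces, _ = gen_transients(TransientSpec(n_cells=1, noise_sd_um=0.0, cell_cv=0.0, seed=0))
        tr = traces[0]
        l0 = np.median(tr.cell_length[:20])
        length = tr.cell_length.copy()
        in_beat4 = (tr.time_s >= 3.05) & (tr.time_s < 4.05)
        length[in_beat4] = l0
        flat = TransientTrace(tr.time_s, length, cell_id="missed")
        with pytest.warns(UserWarning, match="arrhythmic"):
            windows = segment_beats(flat)
        assert len(windows) == 9

    def test_flat_trace_errors(self):
        t = np.arange(0, 10, 0.004)
        with pytest.raises(TransientError, match="flat|detectable"):
            segment_beats(TransientTrace(t, np.full_like(t, 120.0)))

    def test_trace_validation(self):
        t = np.arange(0, 2, 0.004)
        with pytest.raises(TransientError, match="3 beats"):
            TransientTrace(t, np.full_like(t, 1.0))
        bad_t = np.concatenate([np.arange(0, 5, 0.004), np.arange(5, 10, 0.008)])
        with pytest.raises(TransientError, match="uniform"):
            TransientTrace(bad_t, np.zeros_like(bad_t))


class TestLusitropy:
    def test_published_response_magnitude(self):
        """A 21% ttb90 drop (0.50 -> 0.395 s) gives lusitropy 0.21."""
        assert lusitropy(0.50, 0.395) == pytest.approx(0.21)

    def test_no_change_is_zero_and_slowing_is_negative(self):
        assert lusitropy(0.4, 0.4) == 0.0
        assert lusitropy(0.40, 0.436) == pytest.approx(-0.09)

    def test_monotone_decreasing_in_dob_ttb90(self):
        vals = [lusitropy(0.5, x) for x in (0.3, 0.4, 0.5, 0.6)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lusitropy(0.0, 0.4)
        with pytest.raises(ValueError):
            lusitropy(0.4, -0.1)


class TestPairedResponse:
    @staticmethod
    def features(ttb, amp=8.0, ttp=0.15):
        return BeatFeatures(l0=120.0, amplitude_pct=amp, ttp90_s=ttp, ttb90_s=ttb)

    def test_planted_reduction_reaches_two_stars(self):
        """A 20% +/- 2% per-cell ttb90 reduction over 40 cells is p < 0.01."""
        rng = np.random.default_rng(0)
        pre, post = {}, {}
        for i in range(40):
            ttb = 0.45 * (1 + rng.normal(0, 0.05))
            pre[f"c{i}"] = self.features(ttb)
            post[f"c{i}"] = self.features(ttb * (1 - rng.normal(0.20, 0.02)))
        resp = paired_response(pre, post)
        assert resp.p_values["ttb90_s"] < 0.01
        assert resp.stars["ttb90_s"] == "**"
        assert resp.means["lusitropy"] == pytest.approx(0.20, abs=0.01)
        oracle = stats.ttest_rel(
            [post[k].ttb90_s for k in sorted(pre)], [pre[k].ttb90_s for k in sorted(pre)]
        )
        assert resp.p_values["ttb90_s"] == pytest.approx(float(oracle.pvalue))

    def test_null_pairing_p_values_are_calibrated(self):
        """With no planted effect the paired p-value is roughly uniform."""
        rng = np.random.default_rng(1)
        pvals = []
        for rep in range(200):
            pre, post = {}, {}
            for i in range(10):
                pre[f"c{i}"] = self.features(0.45 + rng.normal(0, 0.02))
                post[f"c{i}"] = self.features(0.45 + rng.normal(0, 0.02))
            pvals.append(paired_response(pre, post).p_values["ttb90_s"])
        # Kolmogorov-Smirnov against uniform
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_unpaired_and_too_few_cells(self):
        pre = {"a": self.features(0.4), "b": self.features(0.4), "c": self.features(0.4)}
        post = dict(pre)
        post.pop("c")
        with pytest.raises(ValueError, match="unpaired"):
            paired_response(pre, post)
        with pytest.raises(ValueError, match=">= 3"):
            paired_response({"a": pre["a"], "b": pre["b"]}, {"a": pre["a"], "b": pre["b"]})


class TestGenerateAndRecover:
    def test_zero_noise_features_near_exact(self):
        traces, man = gen_transients(
            TransientSpec(n_cells=1, noise_sd_um=0.0, drift_um=0.0, cell_cv=0.0, seed=0)
        )
        f = trace_features(traces[0])
        dt = 1.0 / 250.0
        assert f.ttp90_s == pytest.approx(0.15, abs=dt)
        assert f.ttb90_s == pytest.approx(0.45, abs=dt)
        assert f.amplitude_pct == pytest.approx(8.0, rel=0.01)

    def test_same_seed_identical_traces(self):
        a, _ = gen_transients(TransientSpec(n_cells=2, seed=5))
        b, _ = gen_transients(TransientSpec(n_cells=2, seed=5))
        np.testing.assert_array_equal(a[0].cell_length, b[0].cell_length)

    def test_infeasible_beat_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            TransientSpec(ttp90_s=0.4, ttb90_s=0.6)

    def test_planted_lusitropy_pipeline(self):
        """ttb90 0.50 -> 0.395 s planted per cell recovers lusitropy 0.21."""
        spec = TransientSpec(ttb90_s=0.50, n_cells=20, cell_cv=0.02, seed=2)
        pre, post, _ = gen_paired_transients(spec, lusitropy=0.21, lusitropy_sd=0.0)
        pre_f = {t.cell_id: trace_features(t) for t in pre}
        post_f = {t.cell_id: trace_features(t) for t in post}
        resp = paired_response(pre_f, post_f)
        assert resp.means["lusitropy"] == pytest.approx(0.21, abs=0.01)
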