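"""Control fitting, dF/F arithmetic, and the three z-score conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberphot import (
    ChunkSelection,
    EventStream,
    FiberphotError,
    RecordingSession,
    TimeSeries,
    apply_chunks,
    compute_dff,
    compute_dff_chunked,
    fit_control,
    zscore,
)
from fiberphot.normalize import MODIFIED_Z_CONSTANT, mad
from fiberphot.preprocess import session_as_single_chunk
from fiberphot.synth import SynthParams, generate_session


def _ts(values, rate=10.0):
    values = np.asarray(values, float)
    return TimeSeries(np.arange(len(values)) / rate, values, rate)


class TestFitControl:
    def test_identity(self, rng):
        c = _ts(rng.normal(10, 1, 500))
        fit = fit_control(c, c)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)

    def test_exact_affine(self, rng):
        c = _ts(rng.normal(10, 1, 500))
        s = c.with_values(3.0 * c.values + 2.0)
        fit = fit_control(c, s)
        assert fit.slope == pytest.approx(3.0, abs=1e-10)
        assert fit.intercept == pytest.approx(2.0, abs=1e-9)
        # FitResult invariant: fitted == slope*control + intercept
        np.testing.assert_allclose(
            fit.fitted_control.values,
            fit.slope * c.values + fit.intercept,
            atol=1e-12,
        )

    def test_noisy_against_closed_form_ols(self):
        rng = np.random.default_rng(99)
        n = 10_000
        c = _ts(rng.normal(5, 1, n))
        s = c.with_values(2.0 * c.values + 1.0 + rng.normal(0, 0.01, n))
        fit = fit_control(c, s)
        assert 1.99 <= fit.slope <= 2.01
        # closed-form least-squares oracle
        x, y = c.values, s.values
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        assert fit.slope == pytest.approx(sxy / sxx, abs=1e-10)
        assert fit.intercept == pytest.approx(y.mean() - (sxy / sxx) * x.mean(), abs=1e-10)

    def test_constant_control_fatal(self):
        c = _ts(np.full(100, 2.0))
        s = _ts(np.arange(100.0))
        with pytest.raises(FiberphotError, match="isosbestic"):
            fit_control(c, s)


class TestComputeDff:
    def test_equal_inputs_give_zero(self, rng):
        s = _ts(rng.uniform(1, 2, 200))
        out = compute_dff(s, s)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_direct_substitution(self):
        s = _ts(np.full(50, 1.1))
        f = _ts(np.full(50, 1.0))
        np.testing.assert_allclose(compute_dff(s, f).values, 0.1, atol=1e-15)

    def test_scalar_loop_oracle(self, rng):
        s = _ts(rng.uniform(1, 3, 300))
        f = _ts(rng.uniform(1, 3, 300))
        out = compute_dff(s, f).values
        expected = np.array(
            [(si - fi) / fi for si, fi in zip(s.values, f.values)]
        )
        np.testing.assert_allclose(out, expected, atol=1e-15)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k=st.floats(1e-3, 1e3), seed=st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, k, seed):
        r = np.random.default_rng(seed)
        s = _ts(r.uniform(1, 3, 100))
        f = _ts(r.uniform(1, 3, 100))
        base = compute_dff(s, f).values
        scaled = compute_dff(s.with_values(k * s.values), f.with_values(k * f.values)).values
        np.testing.assert_allclose(scaled, base, atol=1e-12)

    def test_near_zero_denominator_fatal(self):
        s = _ts(np.ones(50))
        f = _ts(np.ones(50))
        f.values[10] = 0.0
        with pytest.raises(FiberphotError, match="indices"):
            compute_dff(s, f)


def _bleachy_session(n=6000, rate=20.0, seed=0, artifact=None):
    """Signal/control pair with different bleach slopes plus activity."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    activity = 0.05 * (np.sin(0.5 * t) > 0.95)
    control = 0.2 * np.exp(-t / 200) + 0.8
    sig = 0.3 * np.exp(-t / 150) + 1.0 + activity
    if artifact is not None:
        a_t, a_amp, a_w = artifact
        bump = a_amp * np.exp(-0.5 * ((t - a_t) / a_w) ** 2)
        control = control + bump
        sig = sig + bump
    control = control + rng.normal(0, 0.002, n)
    sig = sig + rng.normal(0, 0.002, n)
    return RecordingSession(
        signal=TimeSeries(t, sig, rate), control=TimeSeries(t, control, rate)
    )


class TestComputeDffChunked:
    def test_single_chunk_reduces_to_whole_trace(self):
        sess = _bleachy_session()
        chunked = session_as_single_chunk(sess)
        out = compute_dff_chunked(chunked)
        fit = fit_control(sess.control, sess.signal)
        direct = compute_dff(sess.signal, fit.fitted_control)
        np.testing.assert_allclose(out.values, direct.values, atol=1e-14)
        assert out.chunk_boundaries == ()

    def test_no_step_at_join_on_clean_data(self):
        sess = _bleachy_session(seed=3)
        chunked = apply_chunks(sess, ChunkSelection(((0.0, 150.0), (150.0, 300.0))))
        out = compute_dff_chunked(chunked)
        (b,) = out.chunk_boundaries
        local_sd = np.std(np.diff(out.values[b - 200 : b + 200]))
        step = abs(out.values[b] - out.values[b - 1])
        assert step < 5 * local_sd

    def test_artifact_excision_restores_range(self):
        clean = _bleachy_session(seed=5)
        dirty = _bleachy_session(seed=5, artifact=(150.0, 5.0, 1.0))
        clean_dff = compute_dff_chunked(session_as_single_chunk(clean))
        sel = ChunkSelection(((0.0, 140.0), (160.0, 300.0)))
        excised_dff = compute_dff_chunked(apply_chunks(dirty, sel))
        r_clean = np.ptp(clean_dff.values)
        r_excised = np.ptp(excised_dff.values)
        assert abs(r_excised - r_clean) / r_clean < 0.10

    def test_chunk_error_annotated_with_index(self):
        sess = _bleachy_session()
        chunked = apply_chunks(sess, ChunkSelection(((0.0, 150.0), (150.0, 300.0))))
        flat = chunked.chunks[1][0].with_values(np.full(len(chunked.chunks[1][0]), 1.0))
        import dataclasses

        broken = dataclasses.replace(chunked, chunks=(chunked.chunks[0], (flat, chunked.chunks[1][1])))
        with pytest.raises(FiberphotError, match="chunk 1"):
            compute_dff_chunked(broken)

    def test_no_isosbestic_path(self):
        sess = _bleachy_session()
        out = compute_dff_chunked(session_as_single_chunk(sess), use_isosbestic=False)
        assert np.all(np.isfinite(out.values))


class TestZscore:
    def test_standard_mean_zero_sd_one(self, rng):
        z = zscore(_ts(rng.normal(3, 2, 5000)), "standard")
        assert abs(z.values.mean()) < 1e-10
        assert abs(z.values.std() - 1.0) < 1e-10

    def test_modified_z_printed_constant(self):
        # (0,1,2): median 1, MAD 1 -> +-0.6745 exactly
        z = zscore(_ts([0.0, 1.0, 2.0]), "modified")
        np.testing.assert_allclose(z.values, [-0.6745, 0.0, 0.6745], atol=1e-15)
        assert MODIFIED_Z_CONSTANT == 0.6745

    def test_modified_matches_standard_for_gaussian(self):
        # 0.6745 = Phi^-1(0.75): 0.6745/MAD estimates 1/sigma consistently,
        # so modified-vs-standard regression slope ~ 1 on Gaussian draws
        rng = np.random.default_rng(2024)
        ts = _ts(rng.normal(0, 1, 100_000))
        zs = zscore(ts, "standard").values
        zm = zscore(ts, "modified").values
        slope = np.polyfit(zs, zm, 1)[0]
        assert 0.98 <= slope <= 1.02

    def test_baseline_window_statistics(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(2.0, 0.5, 1000)
        ts = _ts(vals, rate=10.0)  # 100 s
        z = zscore(ts, "baseline", baseline_window=(0.0, 10.0))
        seg = vals[:100]  # [0,10) at 10 Hz
        expected = (vals - seg.mean()) / seg.std()
        np.testing.assert_allclose(z.values, expected, atol=1e-12)

    def test_population_sd_convention_locked(self):
        # ddof=0 scalar-loop oracle
        vals = np.array([1.0, 2.0, 4.0, 8.0])
        z = zscore(_ts(vals), "standard")
        mu = sum(vals) / len(vals)
        sd = (sum((v - mu) ** 2 for v in vals) / len(vals)) ** 0.5
        np.testing.assert_allclose(z.values, (vals - mu) / sd, atol=1e-14)

    @pytest.mark.parametrize("method", ["standard", "modified"])
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(a=st.floats(0.01, 100), b=st.floats(-50, 50), seed=st.integers(0, 2**31 - 1))
    def test_affine_invariance(self, method, a, b, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=500)
        z1 = zscore(_ts(x), method).values
        z2 = zscore(_ts(a * x + b), method).values
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_constant_trace_fatal(self):
        with pytest.raises(FiberphotError, match="constant"):
            zscore(_ts(np.full(100, 3.0)), "standard")
        with pytest.raises(FiberphotError, match="constant"):
            zscore(_ts(np.full(100, 3.0)), "modified")

    def test_mad_definition(self, rng):
        x = rng.normal(size=999)
        assert mad(x) == np.median(np.abs(x - np.median(x)))


class TestDffRecovery:
    def test_dff_beats_raw_signal_on_shared_artifacts(self):
        params = SynthParams(
            duration=300.0,
            rate=20.0,
            transient_times=tuple(np.arange(10.0, 290.0, 7.0)),
            artifact_events=tuple((float(t), 0.3, 0.5) for t in range(20, 290, 40)),
            noise_sd=0.002,
            seed=11,
        )
        session, truth = generate_session(params)
        dff = compute_dff_chunked(session_as_single_chunk(session))
        act = truth.clean_activity_trace
        r_dff = np.corrcoef(dff.values, act)[0, 1]
        r_raw = np.corrcoef(session.signal.values, act)[0, 1]
        assert r_dff >= r_raw
        assert r_dff > 0.8
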