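import numpy as np
import pytest
from scipy.optimize import minimize

from flimpipe.decay import (
    ChannelWaveform,
    LaguerreDeconvolver,
    RawRecord,
    average_lifetime,
    deconvolve_cls,
    demultiplex,
    estimate_snr,
    intensity_ratio,
    process_record,
    process_scan,
    subtract_background,
)
from flimpipe.instrument import InstrumentModel, generate_irf
from flimpipe.laguerre import alpha_for_envelope, build_laguerre_basis
from flimpipe.simulate import generate_waveform


def _record(model, samples, **kw):
    return RawRecord(samples=np.asarray(samples, float), time_base=model.sampling_interval, **kw)


# ---------------------------------------------------------------------------
# background subtraction


def test_constant_offset_removed(model, rng):
    base = rng.normal(0, 0.01, model.record_length)
    rec = _record(model, base + 0.2)
    out = subtract_background(_record(model, base), model)
    out_off = subtract_background(rec, model)
    assert np.allclose(out.samples, out_off.samples, atol=1e-9)


def test_zero_record_stays_zero(model):
    out = subtract_background(_record(model, np.zeros(model.record_length)), model)
    assert np.all(out.samples == 0)


def test_baseline_mean_statistics(model, rng):
    # statistics-of-the-mean oracle: after removing the estimated offset the
    # residual baseline mean is itself a mean of n iid draws
    sigma = 0.02
    n = model.baseline_samples
    rec = _record(model, rng.normal(0.05, sigma, model.record_length))
    out = subtract_background(rec, model)
    m = out.samples[:n].mean()
    assert abs(m) < 1e-12  # the baseline window defines the offset exactly


def test_overlapping_baseline_window_rejected(model):
    rec = _record(model, np.zeros(model.record_length))
    with pytest.raises(ValueError, match="overlaps"):
        subtract_background(rec, model, baseline_window=(0, model.channel_delays[0] + 10))


# ---------------------------------------------------------------------------
# demultiplexing


def test_four_disjoint_pulses_split(model):
    samples = np.zeros(model.record_length)
    for ch in range(4):
        samples[model.channel_delays[ch] + 40] = 1.0 + ch
    waveforms = demultiplex(_record(model, samples), model)
    assert len(waveforms) == 4
    for ch, w in enumerate(waveforms):
        assert w.samples.size == model.samples_per_channel
        assert w.samples.max() == 1.0 + ch
        assert np.argmax(w.samples) == 40


def test_pulse_only_in_ch2(model, rng):
    noise = rng.normal(0, 1e-4, model.record_length)
    samples = noise.copy()
    samples[model.channel_delays[1] + 30] = 1.0
    waveforms = demultiplex(_record(model, samples), model)
    floor = 10 * 1e-4
    assert waveforms[1].samples.max() > 0.5
    for ch in (0, 2, 3):
        assert waveforms[ch].samples.max() < floor


def test_energy_bookkeeping(model, rng):
    samples = np.zeros(model.record_length)
    body = rng.uniform(0, 1, model.record_length - model.baseline_samples)
    samples[model.baseline_samples :] = body
    waveforms = demultiplex(_record(model, samples), model)
    total = sum(w.samples.sum() for w in waveforms)
    assert abs(total - body.sum()) < 1e-9


def test_short_record_rejected(model):
    with pytest.raises(ValueError, match="layout"):
        demultiplex(_record(model, np.zeros(100)), model)


# ---------------------------------------------------------------------------
# SNR estimation


def _waveform_with_noise_segment(model, sigma, peak=1.0, n_noise=24):
    samples = np.zeros(model.samples_per_channel)
    if sigma > 0:
        pattern = np.tile([1.0, -1.0], n_noise // 2)
        pattern = pattern / np.std(pattern, ddof=1)  # exact unit sample-SD
        samples[:n_noise] = pattern * sigma
    samples[n_noise + 50] = peak
    return ChannelWaveform(channel=0, samples=samples, time_base=model.sampling_interval)


def test_snr_formula_60db(model):
    w = _waveform_with_noise_segment(model, 0.001)
    assert abs(estimate_snr(w) - 60.0) < 0.1


def test_snr_formula_30db(model):
    # oracle: 20*log10(1/0.0316) = 30.006
    w = _waveform_with_noise_segment(model, 0.0316)
    assert abs(estimate_snr(w) - 30.0) < 0.1


def test_noiseless_returns_cap(model):
    w = _waveform_with_noise_segment(model, 0.0)
    assert estimate_snr(w) == 120.0


def test_pure_noise_snr_low(model, rng):
    # Monte-Carlo oracle: max of ~500 unit normals is ~3.2-3.5 => ~10-11 dB
    values = []
    for _ in range(50):
        w = ChannelWaveform(0, rng.normal(0, 0.01, model.samples_per_channel), model.sampling_interval)
        values.append(estimate_snr(w))
    assert np.median(values) < 14.0


# ---------------------------------------------------------------------------
# average lifetime and intensity ratios


def test_average_lifetime_truncated_moment():
    dt = 0.08
    tau, horizon = 4.0, 25.0
    t = np.arange(0, horizon, dt)
    h = np.exp(-t / tau)
    # closed-form truncated first moment of the continuous decay
    oracle = tau - horizon * np.exp(-horizon / tau) / (1.0 - np.exp(-horizon / tau))
    assert abs(average_lifetime(h, dt) - oracle) / oracle < 0.01


def test_average_lifetime_concentrated_at_zero():
    h = np.zeros(100)
    h[0] = 5.0
    assert average_lifetime(h, 0.08) == 0.0


def test_average_lifetime_scale_invariant(rng):
    h = np.exp(-np.arange(200) * 0.08 / 2.5)
    for k in (1e-3, 1.0, 47.0):
        assert np.isclose(average_lifetime(k * h, 0.08), average_lifetime(h, 0.08))


def test_average_lifetime_zero_integral_flagged():
    with pytest.raises(ValueError, match="undefined"):
        average_lifetime(np.zeros(10), 0.08)


def test_intensity_ratio_examples():
    assert np.allclose(intensity_ratio([2, 1, 1]), [0.5, 0.25, 0.25])
    assert np.allclose(intensity_ratio([5, 0, 0]), [1, 0, 0])


def test_intensity_ratio_property(rng):
    for _ in range(1000):
        v = rng.uniform(0.01, 10.0, 3)
        assert abs(intensity_ratio(v).sum() - 1.0) < 1e-12


def test_intensity_ratio_errors():
    with pytest.raises(ValueError):
        intensity_ratio([0.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        intensity_ratio([-1.0, 2.0, 1.0])


# ---------------------------------------------------------------------------
# constrained deconvolution


def _mono_exp_window(model, irf, tau):
    t = model.window_times
    y = np.convolve(irf, np.exp(-t / tau))[: t.size]
    return y / y.max()


def test_noiseless_monoexp_recovery(model, irf, deconvolver):
    y = _mono_exp_window(model, irf, 4.0)
    w = ChannelWaveform(0, y, model.sampling_interval)
    fit = deconvolver.fit(w, sigma=0.0)
    assert abs(fit.avg_lifetime - 4.0) / 4.0 < 0.02


def test_zero_waveform_empty_fit(model, irf, deconvolver):
    w = ChannelWaveform(0, np.zeros(model.samples_per_channel), model.sampling_interval)
    fit = deconvolver.fit(w, sigma=0.0)
    assert fit.empty
    assert np.all(fit.coefficients == 0)
    assert fit.integral == 0.0


@pytest.mark.parametrize("tau", [1.0, 3.0, 6.0])
def test_monte_carlo_bias_and_constraints(model, irf, deconvolver, rng, tau):
    y0 = _mono_exp_window(model, irf, tau)
    sigma = 10 ** (-30 / 20.0)
    errors = []
    for _ in range(100):
        y = y0 + rng.normal(0, sigma, y0.size)
        w = ChannelWaveform(0, y, model.sampling_interval)
        fit = deconvolver.fit(w, sigma=sigma)
        errors.append((fit.avg_lifetime - tau) / tau)
        h = fit.fitted_firf
        assert h.min() >= -1e-9
        assert np.max(np.diff(h)) <= 1e-6
    assert abs(np.median(errors)) < 0.05


def test_monotonic_lifetime_estimates(model, irf, deconvolver):
    taus = np.linspace(0.8, 7.5, 12)
    estimates = []
    for tau in taus:
        w = ChannelWaveform(0, _mono_exp_window(model, irf, tau), model.sampling_interval)
        estimates.append(deconvolver.fit(w, sigma=0.0).avg_lifetime)
    assert np.all(np.diff(estimates) > 0)


def _brute_force_cls(A, G, y):
    """Independent QP oracle: SLSQP on the same objective/constraints."""
    H = A.T @ A
    f = A.T @ y

    def obj(c):
        r = A @ c - y
        return 0.5 * float(r @ r)

    def jac(c):
        return H @ c - f

    cons = {"type": "ineq", "fun": lambda c: G @ c, "jac": lambda c: G}
    res = minimize(
        obj,
        np.zeros(A.shape[1]),
        jac=jac,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-16},
    )
    return res.x


def test_cls_matches_brute_force_oracle(rng):
    n, order = 64, 4
    model = InstrumentModel(samples_per_channel=n, irf_center=0.8, irf_fwhm=0.3)
    irf = generate_irf(model)
    basis = build_laguerre_basis(order, alpha_for_envelope(1.0, model.sampling_interval), 2048)
    V = basis.basis[:n]
    A = np.column_stack([np.convolve(irf, V[:, j])[:n] for j in range(order)])
    G = np.vstack([V, V[:-1] - V[1:]])
    for _ in range(10):
        tau = rng.uniform(0.3, 2.0)
        y = np.convolve(irf, np.exp(-np.arange(n) * model.sampling_interval / tau))[:n]
        y = y / y.max() + rng.normal(0, 0.02, n)
        fit = deconvolve_cls(y, irf, basis)
        c_oracle = _brute_force_cls(A, G, y)
        assert np.abs(V @ fit.coefficients - V @ c_oracle).max() < 1e-6


def test_grid_mismatch_rejected(model, irf):
    basis = build_laguerre_basis(4, 0.9, 512)
    with pytest.raises(ValueError, match="time grid"):
        deconvolve_cls(np.zeros(100), irf, basis)


# ---------------------------------------------------------------------------
# per-point composition


def test_process_record_end_to_end(clean_model, deconvolver, rng):
    irf = generate_irf(clean_model)
    lifetimes = [5.0, 4.0, 3.5, 2.5]
    weights = [0.4, 0.3, 0.2, 0.1]
    rec, truth = generate_waveform(lifetimes, weights, irf, clean_model, 40.0, rng)
    meas = process_record(rec, deconvolver, clean_model)
    assert meas is not None
    for k in range(3):
        assert abs(meas.lifetimes[k] - lifetimes[k]) / lifetimes[k] < 0.05
        assert abs(meas.intensity_ratios[k] - truth[f"ratio_ch{k + 1}"]) < 0.02
        assert abs(meas.snr[k] - 40.0) < 4.0
    assert abs(meas.intensity_ratios.sum() - 1.0) < 1e-9


def test_ch4_only_signal_dropped(clean_model, deconvolver, rng):
    irf = generate_irf(clean_model)
    rec, _ = generate_waveform([3, 3, 3, 3], [0, 0, 0, 1.0], irf, clean_model, 40.0, rng)
    assert process_record(rec, deconvolver, clean_model) is None


def test_batch_accounting(clean_model, deconvolver, rng):
    irf = generate_irf(clean_model)
    records = []
    for i in range(6):
        if i == 2:
            rec, _ = generate_waveform([3, 3, 3, 3], [0, 0, 0, 1.0], irf, clean_model, 40.0, rng, point_index=i)
        else:
            rec, _ = generate_waveform([5, 4, 3.5, 2.5], [0.4, 0.3, 0.2, 0.1], irf, clean_model, 40.0, rng, point_index=i)
        records.append(rec)
    df, dropped = process_scan(records, deconvolver, clean_model)
    assert len(df) == 5
    assert dropped == [2]
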