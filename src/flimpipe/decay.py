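"""Waveform processing: background subtraction, demultiplexing, SNR
estimation and constrained-least-squares Laguerre deconvolution.

The fluorescence impulse response h(t) of each spectral channel is expanded
on a discrete Laguerre basis and fitted to the measured window by least
squares subject to h >= 0 and h non-increasing (a convex QP).  The QP is
solved exactly through its dual, which reduces to a non-negative
least-squares problem after a Cholesky change of variables.

Because a single Laguerre time scale cannot represent both sub-ns and
multi-ns decays accurately, the deconvolver keeps a small bank of bases
with geometrically spaced envelope time constants.  For each waveform the
fastest basis whose (cheap, unconstrained) residual is statistically
indistinguishable from the best one is chosen, then refined to the basis
whose envelope matches the estimated lifetime.  Average lifetime is the
first moment of the fitted h over an adaptive horizon with an analytic
exponential-tail correction for the truncated part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import nnls

from .instrument import InstrumentModel, generate_irf
from .laguerre import LaguerreBasis, alpha_for_envelope, build_laguerre_basis

__all__ = [
    "RawRecord",
    "ChannelWaveform",
    "DecayFit",
    "FLImMeasurement",
    "subtract_background",
    "demultiplex",
    "estimate_snr",
    "noise_sigma",
    "average_lifetime",
    "intensity_ratio",
    "deconvolve_cls",
    "LaguerreDeconvolver",
    "process_record",
    "process_scan",
    "MEASUREMENT_COLUMNS",
]

SNR_CAP_DB = 120.0

# ---------------------------------------------------------------------------
# data containers


@dataclass
class RawRecord:
    """One digitized voltage trace holding all time-multiplexed channels."""

    samples: np.ndarray
    time_base: float  # ns per sample
    point_index: int = 0
    flags: tuple = ()

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.point_index}: non-finite samples")


@dataclass
class ChannelWaveform:
    """A single background-subtracted channel window on its own time grid."""

    channel: int  # 0-based (CH1 == 0)
    samples: np.ndarray
    time_base: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.time_base


@dataclass
class DecayFit:
    """Result of constrained Laguerre deconvolution of one channel."""

    coefficients: np.ndarray
    alpha: float
    fitted_firf: np.ndarray  # h on the window grid, >= 0, non-increasing
    reconvolution: np.ndarray
    residual_rms: float
    integral: float
    avg_lifetime: float
    snr: float
    empty: bool = False
    constrained: bool = False


@dataclass
class FLImMeasurement:
    """Six analysis parameters for one scan point (CH1-CH3 only)."""

    point_index: int
    lifetimes: np.ndarray  # ns, CH1..CH3
    intensity_ratios: np.ndarray  # fractions, sum to 1
    snr: np.ndarray  # dB, CH1..CH3
    position: tuple = (np.nan, np.nan)
    flags: tuple = ()


MEASUREMENT_COLUMNS = [
    "point_index",
    "x",
    "y",
    "lifetime_ch1",
    "lifetime_ch2",
    "lifetime_ch3",
    "intratio_ch1",
    "intratio_ch2",
    "intratio_ch3",
    "snr_ch1",
    "snr_ch2",
    "snr_ch3",
    "flags",
]


# ---------------------------------------------------------------------------
# record-level operations


def subtract_background(record: RawRecord, model: InstrumentModel, baseline_window: tuple | None = None) -> RawRecord:
    """Remove the DC background estimated from a signal-free baseline window.

    The window defaults to all samples preceding the first channel window.
    A window overlapping any channel window is rejected.
    """
    first_channel_start = model.channel_delays[0]
    if baseline_window is None:
        baseline_window = (0, first_channel_start)
    lo, hi = baseline_window
    if lo < 0 or hi <= lo:
        raise ValueError("invalid baseline window")
    if hi > first_channel_start:
        raise ValueError(
            f"baseline window {baseline_window} overlaps the first channel "
            f"window starting at sample {first_channel_start}"
        )
    level = float(record.samples[lo:hi].mean())
    return replace(record, samples=record.samples - level)


def demultiplex(record: RawRecord, model: InstrumentModel) -> list:
    """Split a record into its four channel windows (zero-based time grids)."""
    if record.samples.size < model.record_length:
        raise ValueError(
            f"record {record.point_index}: {record.samples.size} samples, "
            f"layout requires {model.record_length}"
        )
    return [
        ChannelWaveform(
            channel=ch,
            samples=record.samples[model.channel_slice(ch)].copy(),
            time_base=model.sampling_interval,
        )
        for ch in range(model.n_channels)
    ]


def noise_sigma(waveform: ChannelWaveform, noise_samples: int) -> float:
    """Noise standard deviation from the pre-onset, signal-free segment."""
    seg = waveform.samples[:noise_samples]
    return float(np.std(seg, ddof=1)) if seg.size > 1 else 0.0


def estimate_snr(
    waveform: ChannelWaveform,
    noise_samples: int = 24,
    cap_db: float = SNR_CAP_DB,
) -> float:
    """SNR in dB: ``20 log10(peak / sigma)`` with sigma from a signal-free
    segment at the start of the (background-subtracted) window.

    A noiseless waveform (sigma == 0) returns ``cap_db``.
    """
    sigma = noise_sigma(waveform, noise_samples)
    peak = float(np.max(waveform.samples))
    if sigma == 0.0:
        return cap_db
    if peak <= 0.0:
        return -cap_db
    return min(cap_db, 20.0 * np.log10(peak / sigma))


def average_lifetime(firf: np.ndarray, dt: float) -> float:
    """First moment of a sampled impulse response over its own support.

    tau = integral(t h dt) / integral(h dt), trapezoid rule.  Scale
    invariant; raises if the integral is not positive.
    """
    h = np.asarray(firf, dtype=float)
    den = np.trapezoid(h, dx=dt)
    if den <= 0:
        raise ValueError("average lifetime undefined: non-positive integral")
    t = np.arange(h.size) * dt
    return float(np.trapezoid(t * h, dx=dt) / den)


def intensity_ratio(integrals) -> np.ndarray:
    """Normalize channel decay integrals into spectral intensity ratios."""
    v = np.asarray(integrals, dtype=float)
    if np.any(v < 0):
        raise ValueError("integrals must be non-negative")
    s = v.sum()
    if s <= 0:
        raise ValueError("intensity ratios undefined: all integrals zero")
    return v / s


# ---------------------------------------------------------------------------
# constrained least squares machinery


class _CLSSystem:
    """Cached matrices for one (IRF, Laguerre basis, window) combination."""

    def __init__(self, irf: np.ndarray, basis: LaguerreBasis, n_window: int):
        if n_window > basis.n_samples:
            raise ValueError("window longer than basis support")
        self.basis = basis
        self.n_window = n_window
        V = basis.basis[:n_window]
        self.V = V
        # causal convolution: rows of h beyond the window cannot influence it
        self.A = np.column_stack(
            [np.convolve(irf, V[:, j])[:n_window] for j in range(basis.order)]
        )
        H = self.A.T @ self.A
        H = H + np.eye(basis.order) * (1e-10 * np.trace(H))
        self.H_cho = cho_factor(H)
        self.R = cholesky(H)  # upper triangular, H = R'R
        # constraint rows G c >= 0: nonnegativity and non-increase of h
        G = np.vstack([V, V[:-1] - V[1:]])
        # Ghat' = R^{-T} G', columns are the dual NNLS design
        self.GhatT = solve_triangular(self.R.T, G.T, lower=True)

    def solve_unconstrained(self, y: np.ndarray) -> np.ndarray:
        return cho_solve(self.H_cho, self.A.T @ y)

    def solve(self, y: np.ndarray, c0: np.ndarray | None = None):
        """Exact QP solution via the dual NNLS; returns (c, constrained)."""
        if c0 is None:
            c0 = self.solve_unconstrained(y)
        h = self.V @ c0
        if h.min() >= -1e-9 and np.max(np.diff(h)) <= 1e-6:
            return c0, False
        z0 = self.R @ c0
        lam, _ = nnls(self.GhatT, -z0)
        z = z0 + self.GhatT @ lam
        c = solve_triangular(self.R, z, lower=False)
        return c, True

    def residual_sq(self, y: np.ndarray, c: np.ndarray) -> float:
        r = y - self.A @ c
        return float(r @ r)


def _tail_corrected_moment(
    V: np.ndarray, c: np.ndarray, dt: float, pad: float = 0.5, mult: float = 6.0
) -> float:
    """First moment of h = V c over an adaptive horizon, with an analytic
    correction for the exponential tail beyond the horizon."""
    n = V.shape[0]
    t = np.arange(n) * dt
    h = np.clip(V @ c, 0.0, None)
    den = np.trapezoid(h, dx=dt)
    if den <= 0:
        return float("nan")
    tw = float(np.trapezoid(t * h, dx=dt) / den)
    for _ in range(2):
        m = int(np.clip((pad + mult * tw) / dt, 24, n))
        he = np.clip(V[:m] @ c, 0.0, None)
        den = np.trapezoid(he, dx=dt)
        if den <= 0:
            return float("nan")
        tw = float(np.trapezoid(t[:m] * he, dx=dt) / den)
        # invert tau_trunc = tau - T e^(-T/tau) / (1 - e^(-T/tau))
        horizon = m * dt
        tau = tw
        for _ in range(5):
            x = horizon / max(tau, 1e-6)
            if x > 40.0:
                break
            tau = tw + horizon * np.exp(-x) / (1.0 - np.exp(-x))
        tw = tau
    return tw


def deconvolve_cls(
    waveform,
    irf: np.ndarray,
    basis: LaguerreBasis,
    snr: float = float("nan"),
    empty_threshold: float = 0.0,
) -> DecayFit:
    """Constrained least-squares deconvolution with a single Laguerre basis.

    Minimizes ``||y - (irf * basis) c||^2`` subject to ``basis c`` being
    nonnegative and non-increasing.  ``waveform`` may be a ChannelWaveform
    or a plain sample array on the same grid as ``irf``.
    """
    if isinstance(waveform, ChannelWaveform):
        y = waveform.samples
        dt = waveform.time_base
    else:
        y = np.asarray(waveform, dtype=float)
        dt = 1.0
    if y.size != irf.size:
        raise ValueError("waveform and IRF must share one time grid")
    sys_ = _CLSSystem(irf, basis, y.size)
    return _finish_fit(sys_, y, dt, snr, empty_threshold)


def _finish_fit(sys_: _CLSSystem, y, dt, snr, empty_threshold) -> DecayFit:
    c, constrained = sys_.solve(y)
    h = np.clip(sys_.V @ c, 0.0, None)
    recon = sys_.A @ c
    resid = y - recon
    integral = float(np.trapezoid(y, dx=dt))
    empty = bool(h.max() <= empty_threshold)
    if empty:
        c = np.zeros_like(c)
        h = np.zeros_like(h)
        recon = np.zeros_like(recon)
        tau = float("nan")
        integral = 0.0
    else:
        tau = _tail_corrected_moment(sys_.V, c, dt)
    return DecayFit(
        coefficients=c,
        alpha=sys_.basis.alpha,
        fitted_firf=h,
        reconvolution=recon,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        integral=integral,
        avg_lifetime=tau,
        snr=snr,
        empty=empty,
        constrained=constrained,
    )


class LaguerreDeconvolver:
    """Multi-scale Laguerre CLS deconvolver for one instrument window.

    Parameters
    ----------
    irf : ndarray
        Sampled instrument response on the channel-window grid, unit area.
    dt : float
        Sampling interval, ns.
    order : int
        Laguerre expansion order (default 12).
    envelopes : sequence of float
        Envelope time constants (ns) of the basis bank.
    selection_kappa : float
        Width, in units of the chi-square standard deviation, of the band
        within which a faster basis is considered as good as the best one.
    """

    def __init__(
        self,
        irf: np.ndarray,
        dt: float,
        order: int = 12,
        envelopes: tuple = (1.0, 2.0, 4.0, 8.0, 16.0),
        selection_kappa: float = 4.0,
        default_envelope: float = 8.0,
    ):
        self.irf = np.asarray(irf, dtype=float)
        self.dt = float(dt)
        self.order = order
        self.envelopes = tuple(sorted(envelopes))
        self.selection_kappa = selection_kappa
        n_window = self.irf.size
        self.systems = []
        for env in self.envelopes:
            alpha = alpha_for_envelope(env, dt)
            n_ext = max(n_window, int(round(24.0 * env / dt)))
            basis = build_laguerre_basis(order, alpha, n_ext)
            self.systems.append(_CLSSystem(self.irf, basis, n_window))
        self._default = int(np.argmin([abs(np.log(e / default_envelope)) for e in self.envelopes]))

    def fit(self, waveform: ChannelWaveform, sigma: float = 0.0, snr: float = float("nan")) -> DecayFit:
        """Deconvolve one channel window; ``sigma`` is the per-sample noise
        standard deviation used for basis selection."""
        y = waveform.samples
        n = y.size
        peak = float(np.max(y)) if y.size else 0.0
        empty_threshold = 5.0 * sigma
        if peak <= empty_threshold:
            sys_ = self.systems[self._default]
            fit = _finish_fit(sys_, np.zeros_like(y), self.dt, snr, 0.0)
            fit.empty = True
            fit.avg_lifetime = float("nan")
            fit.integral = 0.0
            return fit
        cs = [s.solve_unconstrained(y) for s in self.systems]
        res2 = [s.residual_sq(y, c) for s, c in zip(self.systems, cs)]
        tol = min(res2) + self.selection_kappa * sigma * sigma * np.sqrt(2.0 * n) + 1e-30
        best = min(i for i, r in enumerate(res2) if r <= tol)
        tw0 = _tail_corrected_moment(self.systems[best].V, cs[best], self.dt)
        if np.isfinite(tw0) and tw0 > 0:
            nearest = int(np.argmin([abs(np.log(e / tw0)) for e in self.envelopes]))
            best = max(best, nearest)
        return _finish_fit(self.systems[best], y, self.dt, snr, 0.0)


# ---------------------------------------------------------------------------
# per-point composition


def process_record(
    record: RawRecord,
    deconvolver: LaguerreDeconvolver,
    model: InstrumentModel,
    snr_cap_db: float = SNR_CAP_DB,
    include_ch4_in_ratio: bool = False,
):
    """Full per-point chain: background subtraction, demultiplexing, CLS
    deconvolution, lifetime / intensity-ratio / SNR extraction.

    Returns a FLImMeasurement, or None when the point carries no usable
    CH1-CH3 signal (the reason is recorded by the caller).  CH4 is excluded
    from the analysis parameters; its integral can optionally be included
    in the ratio denominator.
    """
    rec = subtract_background(record, model)
    waveforms = demultiplex(rec, model)
    n_noise = model.noise_estimation_samples
    analysis = waveforms[:3]
    sigmas = [noise_sigma(w, n_noise) for w in analysis]
    snrs = [estimate_snr(w, n_noise, snr_cap_db) for w in analysis]
    integrals = []
    lifetimes = []
    flags = list(record.flags)
    for w, sig, snr in zip(analysis, sigmas, snrs):
        fit = deconvolver.fit(w, sigma=sig, snr=snr)
        if fit.empty:
            return None
        lifetimes.append(fit.avg_lifetime)
        integrals.append(max(0.0, float(np.trapezoid(w.samples, dx=w.time_base))))
    denom_integrals = list(integrals)
    if include_ch4_in_ratio:
        denom_integrals.append(
            max(0.0, float(np.trapezoid(waveforms[3].samples, dx=model.sampling_interval)))
        )
    total = sum(denom_integrals)
    if total <= 0:
        return None
    ratios = np.asarray(integrals, dtype=float) / total
    if include_ch4_in_ratio:
        flags.append("ratio_denominator_includes_ch4")
    return FLImMeasurement(
        point_index=record.point_index,
        lifetimes=np.asarray(lifetimes),
        intensity_ratios=ratios,
        snr=np.asarray(snrs),
        flags=tuple(flags),
    )


def process_scan(records, deconvolver, model, **kwargs):
    """Process a batch of records into a measurement table.

    Returns ``(DataFrame, dropped)`` where ``dropped`` lists the point
    indices rejected for lack of analyzable signal.
    """
    import pandas as pd

    rows = []
    dropped = []
    for rec in records:
        m = process_record(rec, deconvolver, model, **kwargs)
        if m is None:
            dropped.append(rec.point_index)
            continue
        rows.append(
            {
                "point_index": m.point_index,
                "x": m.position[0],
                "y": m.position[1],
                "lifetime_ch1": m.lifetimes[0],
                "lifetime_ch2": m.lifetimes[1],
                "lifetime_ch3": m.lifetimes[2],
                "intratio_ch1": m.intensity_ratios[0],
                "intratio_ch2": m.intensity_ratios[1],
                "intratio_ch3": m.intensity_ratios[2],
                "snr_ch1": m.snr[0],
                "snr_ch2": m.snr[1],
                "snr_ch3": m.snr[2],
                "flags": ";".join(m.flags),
            }
        )
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    return df, dropped
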