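"""Instrument model for a time-multiplexed, four-band point-scanning FLIm system.

A single digitized record holds a short baseline segment followed by four
equal-length channel windows; each window contains that spectral band's
impulse response convolved with the system IRF.  Defaults correspond to a
sub-nanosecond pulsed UV excitation system sampled at 80 ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: nominal spectral bands, (center_nm, half_width_nm), CH1..CH4
DEFAULT_BANDS = ((390.0, 20.0), (470.0, 14.0), (542.0, 25.0), (629.0, 26.5))


@dataclass(frozen=True)
class InstrumentModel:
    """Geometry and timing of the simulated/assumed acquisition system.

    Parameters
    ----------
    sampling_interval : float
        Digitizer sampling period in ns (default 0.08, i.e. 80 ps).
    samples_per_channel : int
        Number of samples in each demultiplexed channel window.
    baseline_samples : int
        Signal-free samples at the start of the record, used for
        background estimation.
    irf_fwhm : float
        Full width at half maximum of the Gaussian instrument response, ns.
    irf_center : float
        Position of the IRF peak within a channel window, ns from window
        start.  Samples before the IRF onset act as the in-window noise
        estimation segment.
    background_level : float
        DC offset added to simulated records (volts).
    frame_size : tuple
        (width, height) of the white-light video frames in pixels.
    """

    sampling_interval: float = 0.08
    samples_per_channel: int = 512
    baseline_samples: int = 64
    n_channels: int = 4
    irf_fwhm: float = 0.6
    irf_center: float = 3.0
    channel_bands: tuple = DEFAULT_BANDS
    background_level: float = 0.02
    frame_size: tuple = (1280, 720)

    def __post_init__(self):
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.samples_per_channel < 8:
            raise ValueError("samples_per_channel too small")
        if self.baseline_samples < 1:
            raise ValueError("baseline_samples must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.irf_center <= 0 or self.irf_center >= self.window_duration:
            raise ValueError("irf_center must fall inside the channel window")

    # -- derived layout ----------------------------------------------------

    @property
    def window_duration(self) -> float:
        return self.samples_per_channel * self.sampling_interval

    @property
    def channel_delays(self) -> tuple:
        """Start sample index of each channel window (disjoint, ordered)."""
        return tuple(
            self.baseline_samples + i * self.samples_per_channel
            for i in range(self.n_channels)
        )

    @property
    def record_length(self) -> int:
        return self.baseline_samples + self.n_channels * self.samples_per_channel

    def channel_slice(self, channel: int) -> slice:
        """Slice of the full record occupied by channel ``channel`` (0-based)."""
        start = self.channel_delays[channel]
        return slice(start, start + self.samples_per_channel)

    @property
    def window_times(self) -> np.ndarray:
        """Zero-based time grid of one channel window, ns."""
        return np.arange(self.samples_per_channel) * self.sampling_interval

    @property
    def noise_estimation_samples(self) -> int:
        """In-window samples guaranteed to precede the IRF onset."""
        sigma = self.irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        onset = self.irf_center - 4.0 * sigma
        return max(4, int(onset / self.sampling_interval))


def generate_irf(model: InstrumentModel, n_samples: int | None = None) -> np.ndarray:
    """Sampled Gaussian instrument response, unit area on the window grid.

    Raises
    ------
    ValueError
        If the FWHM is narrower than one sampling interval (the IRF would
        be unresolvable on the grid).
    """
    if model.irf_fwhm <= 0:
        raise ValueError("irf_fwhm must be positive")
    if model.irf_fwhm < model.sampling_interval:
        raise ValueError(
            f"irf_fwhm ({model.irf_fwhm} ns) is below the sampling interval "
            f"({model.sampling_interval} ns); the IRF cannot be resolved"
        )
    n = model.samples_per_channel if n_samples is None else n_samples
    t = np.arange(n) * model.sampling_interval
    sigma = model.irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    irf = np.exp(-0.5 * ((t - model.irf_center) / sigma) ** 2)
    return irf / irf.sum()
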