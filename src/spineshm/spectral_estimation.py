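"""Pulse-averaged spectra, FRF and magnitude-squared coherence.

Each one-second pulse of a recording is one estimation segment: auto-spectra
of the force and of each acceleration channel, and the complex cross-spectra
between them, are averaged across pulses (Welch averaging with a rectangular
window and no overlap -- the multisine excitation is periodic within a pulse,
so the rectangular window is leakage-free by construction).

From the averaged spectra two quantities are derived per sensor:

* the frequency response function (FRF), by default the ratio of output power
  to input power at each frequency (an |H|^2-style convention; a magnitude
  convention, its square root, is available);
* the magnitude-squared coherence |S_fa|^2 / (S_ff * S_aa), which is 1 for a
  noiseless linear system and is degraded by measurement noise.

The FRF is optionally smoothed with a running median whose window shrinks
symmetrically at the edges.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, EstimationError
from .spine_sim import PulseTrainRecording

FRF_CONVENTIONS = ("power", "amplitude")


@dataclass
class SpectralSet:
    """Per-sensor spectral estimates of one recording on a common grid."""

    subject_id: str
    trial_index: int
    frequencies: np.ndarray          # Hz, strictly increasing, in-band
    sensors: tuple[str, ...]
    input_power: np.ndarray          # (n_f,) force^2/Hz
    output_power: np.ndarray         # (n_sensors, n_f) accel^2/Hz
    cross_power: np.ndarray          # (n_sensors, n_f) complex, accel x force / Hz
    n_averages: int
    coherence_defined: bool
    frf: np.ndarray | None = None
    frf_convention: str | None = None
    coherence: np.ndarray | None = None

    @property
    def mean_coherence(self) -> dict[str, float]:
        """Per-sensor mean coherence over the excited band."""
        if self.coherence is None:
            raise EstimationError("coherence has not been computed")
        return {s: float(np.mean(self.coherence[i])) for i, s in enumerate(self.sensors)}


def compute_spectra(
    rec: PulseTrainRecording,
    band: tuple[float, float] = (1.0, 2000.0),
    window: str = "boxcar",
) -> SpectralSet:
    """Estimate pulse-averaged auto- and cross-spectra of a recording.

    One pulse is one segment (no overlap).  The frequency grid is the DFT
    grid of a single pulse restricted to ``band``.  With fewer than two
    pulses the spectra are still returned but flagged coherence-undefined.
    """
    f_min, f_max = band
    nyquist = rec.sample_rate / 2
    if not (0 < f_min < f_max < nyquist):
        raise ConfigurationError(
            f"band [{f_min}, {f_max}] must lie inside (0, {nyquist}) Hz"
        )
    nper = rec.samples_per_pulse
    win = signal.get_window(window, nper) if window != "boxcar" else np.ones(nper)
    freqs = np.fft.rfftfreq(nper, d=1.0 / rec.sample_rate)
    keep = (freqs >= f_min) & (freqs <= f_max)
    # Welch periodogram average, one pulse per segment, density scaling;
    # the factor 2 folds the negative frequencies (band excludes DC/Nyquist).
    scale = 2.0 / (rec.sample_rate * np.sum(win**2))
    F = np.fft.rfft(rec.force.reshape(rec.n_pulses, nper) * win, axis=-1)[:, keep]
    accels = np.stack([rec.accel[label] for label in rec.sensors])
    A = np.fft.rfft(accels.reshape(len(rec.sensors), rec.n_pulses, nper) * win, axis=-1)[
        :, :, keep
    ]
    pff = scale * np.mean(np.abs(F) ** 2, axis=0)
    out_power = scale * np.mean(np.abs(A) ** 2, axis=1)
    cross = scale * np.mean(np.conj(F)[None, :, :] * A, axis=1)
    return SpectralSet(
        subject_id=rec.subject_id,
        trial_index=rec.trial_index,
        frequencies=freqs[keep],
        sensors=rec.sensors,
        input_power=pff,
        output_power=out_power,
        cross_power=cross,
        n_averages=rec.n_pulses,
        coherence_defined=rec.n_pulses >= 2,
    )


def compute_frf(spec: SpectralSet, convention: str = "power") -> SpectralSet:
    """Fill the FRF: output power over input power per frequency per sensor.

    ``convention="power"`` keeps the power ratio (behaves like |H|^2);
    ``convention="amplitude"`` takes its square root (behaves like |H|).
    PEAK is invariant to the choice; AUC and RMS are not.
    """
    if convention not in FRF_CONVENTIONS:
        raise ConfigurationError(f"convention must be one of {FRF_CONVENTIONS}")
    if np.any(spec.input_power <= 0):
        bin_hz = spec.frequencies[np.argmax(spec.input_power <= 0)]
        raise EstimationError(f"zero input power at in-band frequency {bin_hz:g} Hz")
    ratio = spec.output_power / spec.input_power[None, :]
    frf = ratio if convention == "power" else np.sqrt(ratio)
    return dataclasses.replace(spec, frf=frf, frf_convention=convention)


def compute_coherence(spec: SpectralSet) -> SpectralSet:
    """Fill the magnitude-squared coherence from the averaged spectra.

    Coherence from a single segment is identically 1 and meaningless, so at
    least two averages are required.
    """
    if not spec.coherence_defined or spec.n_averages < 2:
        raise EstimationError(
            f"coherence undefined with {spec.n_averages} pulse average(s); need >= 2"
        )
    denom = spec.input_power[None, :] * spec.output_power
    coh = np.abs(spec.cross_power) ** 2 / denom
    if np.any(coh > 1 + 1e-9) or np.any(coh < -1e-9):
        raise EstimationError("coherence left [0, 1] beyond numerical slack")
    return dataclasses.replace(spec, coherence=np.clip(coh, 0.0, 1.0))


def sliding_median(values: np.ndarray, kernel_bins: int) -> np.ndarray:
    """Running median with symmetric shrinking windows at the edges.

    At index i the window is values[i-h : i+h+1] with
    h = min(i, n-1-i, (kernel_bins-1)//2), so the endpoints are their own
    medians and no padding is invented.
    """
    if kernel_bins < 1 or kernel_bins % 2 == 0:
        raise ConfigurationError(f"kernel_bins must be odd and >= 1, got {kernel_bins}")
    values = np.asarray(values, dtype=float)
    n = values.size
    if kernel_bins > n:
        raise ConfigurationError(f"kernel_bins {kernel_bins} exceeds grid length {n}")
    if kernel_bins == 1:
        return values.copy()
    half = (kernel_bins - 1) // 2
    out = signal.medfilt(values, kernel_size=kernel_bins)
    # medfilt zero-pads; recompute the edge bins with shrinking windows
    for i in range(half):
        out[i] = np.median(values[: 2 * i + 1])
        out[n - 1 - i] = np.median(values[n - 1 - 2 * i:])
    return out


def smooth_frf(spec: SpectralSet, kernel_bins: int = 5) -> SpectralSet:
    """Median-smooth the FRF per sensor; ``kernel_bins=1`` is the identity."""
    if spec.frf is None:
        raise EstimationError("FRF has not been computed")
    smoothed = np.vstack([sliding_median(row, kernel_bins) for row in spec.frf])
    return dataclasses.replace(spec, frf=smoothed)
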