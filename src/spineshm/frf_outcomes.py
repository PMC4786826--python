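"""Scalar FRF outcomes (PEAK, AUC, RMS), coherence QC, and trial averaging.

Each sensor's smoothed FRF is reduced to three scalars:

* PEAK -- the frequency at which the FRF attains its global maximum
  (ties broken toward the lowest frequency);
* AUC  -- the trapezoidal integral of the FRF over the excited band;
* RMS  -- the root mean square of the FRF across in-band frequency bins.

Sensors whose mean coherence falls below a threshold are excluded from
analysis (in the in-vivo protocol the most distal sensor fails this check
because of soft-tissue attenuation).  A subject's three trials are averaged
per sensor; a sensor excluded in any trial is excluded for the subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import AnalysisError
from .spectral_estimation import SpectralSet

logger = logging.getLogger(__name__)

OUTCOMES = ("PEAK", "AUC", "RMS")


@dataclass
class SensorOutcomes:
    sensor: str
    peak_hz: float
    auc: float
    rms: float
    mean_coherence: float
    included: bool


@dataclass
class SubjectOutcomes:
    """Per-trial sensor outcomes and their per-sensor trial means."""

    subject_id: str
    trials: list[dict[str, SensorOutcomes]]   # one dict per trial, keyed by sensor
    means: dict[str, dict[str, float]]        # sensor -> outcome name -> trial mean
    included_sensors: tuple[str, ...]

    def outcome(self, sensor: str, name: str) -> float:
        return self.means[sensor][name]


def peak_frequency(frequencies: np.ndarray, frf: np.ndarray) -> float:
    """Frequency of the global FRF maximum; the lowest frequency wins ties."""
    frequencies = np.asarray(frequencies, dtype=float)
    frf = np.asarray(frf, dtype=float)
    if frf.size == 0:
        raise AnalysisError("cannot locate a peak on an empty grid")
    return float(frequencies[int(np.argmax(frf))])


def area_under_curve(frequencies: np.ndarray, frf: np.ndarray) -> float:
    """Trapezoidal integral of the FRF over the frequency grid."""
    frequencies = np.asarray(frequencies, dtype=float)
    frf = np.asarray(frf, dtype=float)
    if frf.size < 2:
        raise AnalysisError("AUC needs at least two grid points")
    if np.any(np.diff(frequencies) <= 0):
        raise AnalysisError("frequency grid must be strictly increasing")
    return float(np.trapezoid(frf, frequencies))


def root_mean_square(frf: np.ndarray) -> float:
    """RMS of the FRF across in-band frequency bins."""
    frf = np.asarray(frf, dtype=float)
    if frf.size == 0:
        raise AnalysisError("RMS of an empty FRF is undefined")
    return float(np.sqrt(np.mean(frf**2)))


def qc_sensors(mean_coherence: dict[str, float], threshold: float = 0.5) -> dict[str, bool]:
    """Flag each sensor as included iff its mean coherence is >= threshold."""
    if not (0 < threshold < 1):
        raise AnalysisError(f"QC threshold must lie in (0, 1), got {threshold}")
    flags = {s: c >= threshold for s, c in mean_coherence.items()}
    for s, ok in flags.items():
        if not ok:
            logger.info(
                "sensor %s excluded: mean coherence %.3f < %.3f",
                s, mean_coherence[s], threshold,
            )
    return flags


def trial_outcomes(spec: SpectralSet, qc_threshold: float = 0.5) -> dict[str, SensorOutcomes]:
    """Reduce one trial's smoothed FRF to per-sensor outcomes with QC flags."""
    if spec.frf is None or spec.coherence is None:
        raise AnalysisError("trial requires both FRF and coherence")
    mean_coh = spec.mean_coherence
    flags = qc_sensors(mean_coh, qc_threshold)
    out: dict[str, SensorOutcomes] = {}
    for i, sensor in enumerate(spec.sensors):
        row = spec.frf[i]
        out[sensor] = SensorOutcomes(
            sensor=sensor,
            peak_hz=peak_frequency(spec.frequencies, row),
            auc=area_under_curve(spec.frequencies, row),
            rms=root_mean_square(row),
            mean_coherence=mean_coh[sensor],
            included=flags[sensor],
        )
    return out


def summarize_subject(
    trial_specs: list[SpectralSet], qc_threshold: float = 0.5
) -> SubjectOutcomes:
    """Average per-sensor outcomes across a subject's trials.

    All trials must share the frequency grid.  A sensor failing QC in any
    trial is excluded for the subject (stricter than per-trial exclusion,
    chosen for reproducibility).  Raises if no sensor passes.
    """
    if not trial_specs:
        raise AnalysisError("at least one trial is required")
    grid = trial_specs[0].frequencies
    for spec in trial_specs[1:]:
        if spec.frequencies.shape != grid.shape or not np.allclose(spec.frequencies, grid):
            raise AnalysisError("trials have mismatched frequency grids")
    trials = [trial_outcomes(spec, qc_threshold) for spec in trial_specs]
    sensors = trial_specs[0].sensors
    included = tuple(
        s for s in sensors if all(t[s].included for t in trials)
    )
    if not included:
        raise AnalysisError("no sensors pass QC for this subject")
    means = {
        s: {
            "PEAK": float(np.mean([t[s].peak_hz for t in trials])),
            "AUC": float(np.mean([t[s].auc for t in trials])),
            "RMS": float(np.mean([t[s].rms for t in trials])),
            "coherence": float(np.mean([t[s].mean_coherence for t in trials])),
        }
        for s in included
    }
    return SubjectOutcomes(
        subject_id=trial_specs[0].subject_id,
        trials=trials,
        means=means,
        included_sensors=included,
    )
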