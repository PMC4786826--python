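"""End-to-end orchestration: recording -> spectra -> outcomes -> twin report."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import AnalysisError
from .frf_outcomes import SubjectOutcomes, summarize_subject
from .spectral_estimation import (
    SpectralSet,
    compute_coherence,
    compute_frf,
    compute_spectra,
    smooth_frf,
)
from .spine_sim import PulseTrainRecording, SyntheticCohort
from .twin_comparison import TwinPairResult, cohort_report, pair_differences


def analyze_recording(
    rec: PulseTrainRecording,
    band: tuple[float, float] = (1.0, 2000.0),
    kernel_bins: int = 5,
    convention: str = "power",
    window: str = "boxcar",
) -> SpectralSet:
    """Spectra, coherence and median-smoothed FRF for one recording."""
    spec = compute_spectra(rec, band=band, window=window)
    spec = compute_frf(spec, convention=convention)
    spec = compute_coherence(spec)
    return smooth_frf(spec, kernel_bins=kernel_bins)


def analyze_subject(
    recordings: list[PulseTrainRecording],
    qc_threshold: float = 0.5,
    **spectral_kwargs,
) -> SubjectOutcomes:
    """Trial-averaged outcomes for one subject's recordings."""
    if not recordings:
        raise AnalysisError("subject has no recordings")
    specs = [analyze_recording(r, **spectral_kwargs) for r in recordings]
    return summarize_subject(specs, qc_threshold=qc_threshold)


def cohort_pair_differences(
    cohort: SyntheticCohort,
    qc_threshold: float = 0.5,
    **spectral_kwargs,
) -> list[TwinPairResult]:
    """Per-pair signed outcome differences for a simulated cohort."""
    outcomes: dict[str, SubjectOutcomes] = {
        m.subject_id: analyze_subject(
            cohort.recordings_for(m.subject_id), qc_threshold, **spectral_kwargs
        )
        for m in cohort.members
    }
    pairs: list[TwinPairResult] = []
    by_pair: dict[str, list] = {}
    for m in cohort.members:
        by_pair.setdefault(m.pair_id, []).append(m)
    for pair_id, twins in by_pair.items():
        a, b = sorted(twins, key=lambda m: m.subject_id)
        pairs.append(
            pair_differences(
                outcomes[a.subject_id], outcomes[b.subject_id],
                pair_id=pair_id, group=a.group,
            )
        )
    return pairs


def analyze_cohort(
    cohort: SyntheticCohort,
    qc_threshold: float = 0.5,
    method: str = "paired-t",
    covariates: dict[str, np.ndarray] | None = None,
    alpha: float = 0.05,
    sensors: tuple[str, ...] | None = None,
    **spectral_kwargs,
) -> pd.DataFrame:
    """Full pipeline on a simulated cohort, ending in the group-test report."""
    pairs = cohort_pair_differences(cohort, qc_threshold, **spectral_kwargs)
    kw = {} if sensors is None else {"sensors": sensors}
    return cohort_report(pairs, method=method, covariates=covariates, alpha=alpha, **kw)
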