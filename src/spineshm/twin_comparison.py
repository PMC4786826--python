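"""Within-pair differences and group-level tests on FRF outcomes.

Monozygotic twin pairs are classified as structurally concordant or
discordant on imaging.  For each pair the signed difference of every
trial-averaged outcome (PEAK, AUC, RMS) is computed per sensor (lower
subject id minus higher, a fixed convention), and for each group x outcome
x sensor cell the null hypothesis that the mean within-pair difference is
zero is tested -- by a one-sample (paired) t-test, or by an ANCOVA-style
linear model of the differences on an intercept plus pair-level covariates
(pair-mean BMI by default), testing the intercept.

The expectation under the structural-health-monitoring hypothesis: no
outcome differs in concordant pairs, while PEAK differs in discordant pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AnalysisError, FormatError
from .frf_outcomes import OUTCOMES, SubjectOutcomes

CONCORDANT, DISCORDANT = "Concordant", "Discordant"
ANALYSIS_SENSORS = ("L1", "L2", "L3", "L4")

_METADATA_COLUMNS = (
    "subject_id", "pair_id", "sex", "age", "bmi",
    "selfreport_concordance", "mri_concordance", "status_note",
)


@dataclass(frozen=True)
class SubjectMetadata:
    subject_id: str
    pair_id: str
    sex: str
    age: float
    bmi: float
    selfreport_concordance: str
    mri_concordance: str
    status_note: str


@dataclass
class TwinPairResult:
    """Signed per-sensor outcome differences within one pair (twin A - twin B,
    A being the lower subject id), with the concordance label used for
    grouping."""

    pair_id: str
    group: str
    subject_a: str
    subject_b: str
    differences: dict[str, dict[str, float]]  # sensor -> outcome -> difference

    @property
    def sensors(self) -> tuple[str, ...]:
        return tuple(self.differences.keys())


@dataclass
class GroupTestResult:
    group: str
    outcome: str
    sensor: str
    mean_difference: float
    test_statistic: float
    p_value: float
    method: str
    n_pairs: int


def parse_metadata(path: str | Path) -> tuple[list[SubjectMetadata], dict[str, int]]:
    """Read a subject metadata table and derive cohort counts.

    The table must carry the columns subject_id, pair_id, sex, age, bmi,
    selfreport_concordance, mri_concordance, status_note; exactly two
    subjects per pair, twins of a pair sharing the MRI concordance label.
    Returns the records plus counts of subjects and of pairs by self-report
    and by MRI concordance.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: not a readable metadata table ({exc})") from exc
    missing = set(_METADATA_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    if table.empty:
        raise FormatError(f"{path}: metadata table has no rows")
    records = [
        SubjectMetadata(
            subject_id=str(r.subject_id), pair_id=str(r.pair_id), sex=str(r.sex),
            age=float(r.age), bmi=float(r.bmi),
            selfreport_concordance=str(r.selfreport_concordance),
            mri_concordance=str(r.mri_concordance), status_note=str(r.status_note),
        )
        for r in table.itertuples()
    ]
    by_pair: dict[str, list[SubjectMetadata]] = {}
    for rec in records:
        by_pair.setdefault(rec.pair_id, []).append(rec)
    for pair_id, twins in by_pair.items():
        if len(twins) != 2:
            raise FormatError(f"pair {pair_id} has {len(twins)} subjects; expected 2")
        if twins[0].mri_concordance != twins[1].mri_concordance:
            raise FormatError(f"pair {pair_id}: twins disagree on MRI concordance")
    counts = {
        "n_subjects": len(records),
        "n_pairs": len(by_pair),
        "pairs_selfreport_concordant": sum(
            1 for twins in by_pair.values()
            if twins[0].selfreport_concordance == CONCORDANT
        ),
        "pairs_selfreport_discordant": sum(
            1 for twins in by_pair.values()
            if twins[0].selfreport_concordance == DISCORDANT
        ),
        "pairs_mri_concordant": sum(
            1 for twins in by_pair.values() if twins[0].mri_concordance == CONCORDANT
        ),
        "pairs_mri_discordant": sum(
            1 for twins in by_pair.values() if twins[0].mri_concordance == DISCORDANT
        ),
    }
    return records, counts


def reference_metadata_path() -> Path:
    """Path of the packaged twin-study metadata table."""
    return Path(resources.files("spineshm").joinpath("data/twin_metadata.csv"))


def load_reference_metadata() -> tuple[list[SubjectMetadata], dict[str, int]]:
    """Parse the packaged twin-study metadata table."""
    return parse_metadata(reference_metadata_path())


def survey_response_summary() -> dict[str, float]:
    """Recruitment-survey counts and the response rate in percent."""
    import json

    raw = resources.files("spineshm").joinpath("data/recruitment.json").read_text()
    counts = json.loads(raw)
    out = dict(counts)
    out["response_rate_pct"] = round(
        100.0 * counts["individuals_responded"] / counts["individuals_approached"], 1
    )
    return out


def pair_differences(
    out_a: SubjectOutcomes,
    out_b: SubjectOutcomes,
    pair_id: str,
    group: str,
) -> TwinPairResult:
    """Signed trial-mean outcome differences per sensor within one pair.

    The twin with the lower subject id is subtracted from first; only
    sensors included for both twins contribute.
    """
    if out_a.subject_id > out_b.subject_id:
        out_a, out_b = out_b, out_a
    shared = [s for s in out_a.included_sensors if s in out_b.included_sensors]
    if not shared:
        raise AnalysisError(f"pair {pair_id}: no overlapping included sensors")
    diffs = {
        s: {name: out_a.outcome(s, name) - out_b.outcome(s, name) for name in OUTCOMES}
        for s in shared
    }
    return TwinPairResult(
        pair_id=pair_id, group=group,
        subject_a=out_a.subject_id, subject_b=out_b.subject_id,
        differences=diffs,
    )


def _one_sample_t(values: np.ndarray) -> tuple[float, float]:
    """One-sample two-sided t-test of mean zero; degenerate (zero-variance)
    samples report t=0, p=1 with a warning."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise AnalysisError("need at least 2 pairs for a t-test")
    if np.ptp(values) == 0 and values[0] == 0:
        warnings.warn("all differences are exactly zero; reporting p=1", stacklevel=2)
        return 0.0, 1.0
    if np.std(values, ddof=1) == 0:
        warnings.warn("zero variance in differences; reporting p=1", stacklevel=2)
        return 0.0, 1.0
    t, p = stats.ttest_1samp(values, popmean=0.0)
    return float(t), float(p)


def _ancova(values: np.ndarray, covariates: np.ndarray) -> tuple[float, float]:
    """Linear model of the differences on an intercept plus centred pair-level
    covariates; the intercept's two-sided t-test is reported."""
    import statsmodels.api as sm

    values = np.asarray(values, dtype=float)
    if np.std(values, ddof=1) == 0:
        warnings.warn("zero variance in differences; reporting p=1", stacklevel=2)
        return 0.0, 1.0
    X = np.column_stack([covariates - covariates.mean(axis=0)])
    X = sm.add_constant(X)
    fit = sm.OLS(values, X).fit()
    return float(fit.tvalues[0]), float(fit.pvalues[0])


def test_group_differences(
    pairs: list[TwinPairResult],
    method: str = "paired-t",
    covariates: dict[str, np.ndarray] | None = None,
    sensors: tuple[str, ...] = ANALYSIS_SENSORS,
) -> list[GroupTestResult]:
    """Test H0 "mean within-pair difference = 0" per group x outcome x sensor.

    ``method`` is "paired-t" (one-sample t on the differences) or "ancova"
    (intercept test of a linear model with pair-level covariates, given as
    {pair_id: covariate vector}).  Two-sided p-values, uncorrected.
    """
    if method not in ("paired-t", "ancova"):
        raise AnalysisError(f"unknown method {method!r}")
    results: list[GroupTestResult] = []
    for group in (CONCORDANT, DISCORDANT):
        group_pairs = [p for p in pairs if p.group == group]
        if not group_pairs:
            continue
        if len(group_pairs) < 2:
            raise AnalysisError(f"group {group} has {len(group_pairs)} pair(s); need >= 2")
        for outcome in OUTCOMES:
            for sensor in sensors:
                usable = [p for p in group_pairs if sensor in p.differences]
                if len(usable) < 2:
                    raise AnalysisError(
                        f"{group}/{outcome}/{sensor}: fewer than 2 pairs with data"
                    )
                values = np.array([p.differences[sensor][outcome] for p in usable])
                if method == "paired-t":
                    t, p = _one_sample_t(values)
                else:
                    if covariates is None:
                        raise AnalysisError("ancova requires pair-level covariates")
                    cov = np.array([covariates[pr.pair_id] for pr in usable], dtype=float)
                    t, p = _ancova(values, cov.reshape(len(usable), -1))
                results.append(
                    GroupTestResult(
                        group=group, outcome=outcome, sensor=sensor,
                        mean_difference=float(values.mean()),
                        test_statistic=t, p_value=p,
                        method=method, n_pairs=len(usable),
                    )
                )
    return results


test_group_differences.__test__ = False  # not a pytest test


def cohort_report(
    pairs: list[TwinPairResult],
    method: str = "paired-t",
    covariates: dict[str, np.ndarray] | None = None,
    alpha: float = 0.05,
    sensors: tuple[str, ...] = ANALYSIS_SENSORS,
) -> pd.DataFrame:
    """Group x outcome x sensor grid of mean differences and p-values.

    One row per cell (2 groups x 3 outcomes x len(sensors) sensors when both
    groups are present), with a significance flag at ``alpha``.
    """
    if not pairs:
        raise AnalysisError("no pairs to report on")
    results = test_group_differences(pairs, method=method, covariates=covariates,
                                     sensors=sensors)
    rows = [
        {
            "group": r.group, "outcome": r.outcome, "sensor": r.sensor,
            "mean_difference": r.mean_difference,
            "test_statistic": r.test_statistic,
            "p_value": r.p_value,
            "significant": r.p_value < alpha,
            "n_pairs": r.n_pairs,
            "method": r.method,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
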