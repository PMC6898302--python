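"""Agreement, reproducibility, correlation and diagnostic-accuracy statistics.

These are the evaluation statistics used to compare the OCT-derived NFL_MD
against the perimetric VF_MD and against micron-scale thickness
parameters: stage-stratified differences and Bland-Altman limits,
test-retest reproducibility as the RMS residual of a per-eye linear trend,
ICC(2,1) repeatability, cluster-bootstrap correlation inference (both eyes
of a participant are correlated, so resampling is by participant), and
AROC with sensitivity at fixed-specificity cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .diagnostics import DiagnosticCutoffs

__all__ = [
    "VisitSeries",
    "AgreementReport",
    "CorrelationResult",
    "CorrelationComparison",
    "RocResult",
    "difference_by_stage",
    "rms_residual_reproducibility",
    "icc_repeatability",
    "clustered_correlation",
    "compare_correlations",
    "aroc_sensitivity",
    "mcnemar_sensitivity",
]

DEFAULT_SEED = 20191206


@dataclass(frozen=True)
class VisitSeries:
    """Paired OCT + VF measurements of one eye over consecutive visits."""

    eye_id: str
    participant_id: str
    times: np.ndarray                 # years from baseline, strictly increasing
    vf_md: np.ndarray                 # dB
    nfl_md: np.ndarray                # dB
    overall_nflt: np.ndarray | None = None   # µm
    inferior_nflt: np.ndarray | None = None  # µm
    stage: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        for name in ("vf_md", "nfl_md", "overall_nflt", "inferior_nflt"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != t.shape:
                    raise ValueError(f"{name} must align with times for eye {self.eye_id!r}")
        if t.size < 2:
            raise ValueError(f"eye {self.eye_id!r}: need at least 2 visits")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"eye {self.eye_id!r}: visit times must be strictly increasing")

    @property
    def n_visits(self) -> int:
        return int(self.times.size)

    def parameter(self, name: str) -> np.ndarray:
        value = getattr(self, name, None)
        if value is None:
            raise KeyError(f"series for eye {self.eye_id!r} has no parameter {name!r}")
        return value


@dataclass(frozen=True)
class AgreementReport:
    """Stage-stratified NFL_MD − VF_MD differences and Bland-Altman summary."""

    stage_mean: Mapping[str, float]        # dB, per stage
    stage_sd: Mapping[str, float]          # dB, RMS-pooled per stage
    stage_n_eyes: Mapping[str, int]
    bias: float                            # dB, mean over eyes (all stages)
    sd_of_differences: float               # dB, SD over per-eye mean differences
    loa_low: float
    loa_high: float


def difference_by_stage(series: Sequence[VisitSeries]) -> AgreementReport:
    """NFL_MD − VF_MD agreement, visit-averaged per eye then stage-stratified.

    Each eye contributes its mean over-visits difference; stage means
    average those per-eye means. The per-stage SD pools the visit-level
    differences about the stage mean by root mean square. Eyes with
    missing pairs are skipped with a warning. The Bland-Altman summary
    (bias, ±1.96·SD limits) is computed over all eyes' mean differences.
    """
    eye_means: list[float] = []
    by_stage: dict[str, list[float]] = {}
    by_stage_visits: dict[str, list[float]] = {}
    for s in series:
        diffs = s.nfl_md - s.vf_md
        if np.any(~np.isfinite(diffs)):
            warnings.warn(f"eye {s.eye_id!r} skipped: incomplete NFL_MD/VF_MD pairs",
                          stacklevel=2)
            continue
        d_mean = float(diffs.mean())
        eye_means.append(d_mean)
        stage = s.stage or "unstaged"
        by_stage.setdefault(stage, []).append(d_mean)
        by_stage_visits.setdefault(stage, []).extend(diffs.tolist())
    if not eye_means:
        raise ValueError("no complete series")

    stage_mean = {k: float(np.mean(v)) for k, v in by_stage.items()}
    stage_sd = {
        k: float(np.sqrt(np.mean((np.asarray(by_stage_visits[k]) - stage_mean[k]) ** 2)))
        for k in by_stage
    }
    stage_n = {k: len(v) for k, v in by_stage.items()}
    means = np.asarray(eye_means)
    bias = float(means.mean())
    sd = float(means.std(ddof=1)) if means.size > 1 else 0.0
    return AgreementReport(
        stage_mean=stage_mean, stage_sd=stage_sd, stage_n_eyes=stage_n,
        bias=bias, sd_of_differences=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
    )


def rms_residual_reproducibility(series: Sequence[VisitSeries], parameter: str) -> float:
    """Test-retest variability as the pooled RMS residual about each eye's linear trend.

    Per eye, the parameter is regressed on visit time by OLS and the
    residual variance uses the regression denominator n − 2; eyes
    contribute equally and are pooled by root mean square. Eyes with fewer
    than 3 visits are excluded with a warning.
    """
    per_eye_var: list[float] = []
    for s in series:
        if s.n_visits < 3:
            warnings.warn(f"eye {s.eye_id!r} excluded: fewer than 3 visits", stacklevel=2)
            continue
        y = s.parameter(parameter)
        t = s.times
        if np.ptp(t) == 0:
            raise ValueError(f"eye {s.eye_id!r}: all visit times identical")
        coef = np.polyfit(t, y, 1)
        resid = y - np.polyval(coef, t)
        per_eye_var.append(float(np.sum(resid**2) / (s.n_visits - 2)))
    if not per_eye_var:
        raise ValueError("no series with >= 3 visits")
    return float(np.sqrt(np.mean(per_eye_var)))


def icc_repeatability(measurements: np.ndarray | Sequence[Sequence[float]]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``measurements`` is an (eyes × repeats) array with complete data
    (≥ 5 eyes, ≥ 2 repeats each).
    """
    import pingouin as pg

    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 5 or m.shape[1] < 2:
        raise ValueError("need a complete (>=5 eyes) x (>=2 repeats) array")
    if np.allclose(m, m.flat[0]):
        raise ValueError("zero total variance")
    n_eyes, n_rep = m.shape
    long = pd.DataFrame({
        "eye": np.repeat(np.arange(n_eyes), n_rep),
        "repeat": np.tile(np.arange(n_rep), n_eyes),
        "value": m.ravel(),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(data=long, targets="eye", raters="repeat",
                                   ratings="value")
    # absolute-agreement single-measurement row; label differs across versions
    row = table[table["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


@dataclass(frozen=True)
class CorrelationResult:
    estimate: float
    ci_low: float
    ci_high: float
    kind: str
    n_boot: int
    n_clusters: int


def _corr(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    if kind == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if kind == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError("kind must be 'pearson' or 'spearman'")


def _cluster_indices(participant_ids: np.ndarray) -> list[np.ndarray]:
    order = pd.Series(range(len(participant_ids))).groupby(
        pd.Series(participant_ids), sort=False
    )
    return [np.asarray(idx) for _, idx in order.groups.items()]


def _bootstrap_stat(clusters: list[np.ndarray], n_boot: int, rng, fn) -> np.ndarray:
    n = len(clusters)
    out = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n, size=n)
        idx = np.concatenate([clusters[i] for i in pick])
        out[b] = fn(idx)
    return out


def clustered_correlation(x: Sequence[float], y: Sequence[float],
                          participant_ids: Sequence, kind: str = "pearson",
                          n_boot: int = 2000, seed: int = DEFAULT_SEED,
                          ci: float = 0.95) -> CorrelationResult:
    """Correlation with a percentile-bootstrap CI resampling participants.

    The point estimate is the plain (unclustered) coefficient; the CI
    resamples whole participants so fellow eyes stay together.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pid = np.asarray(participant_ids)
    if not (x.shape == y.shape == pid.shape):
        raise ValueError("x, y and participant_ids must align")
    if x.size < 10:
        raise ValueError("need at least 10 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    estimate = _corr(x, y, kind)
    clusters = _cluster_indices(pid)
    rng = np.random.default_rng(seed)

    def stat(idx: np.ndarray) -> float:
        xs, ys = x[idx], y[idx]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            return np.nan
        return _corr(xs, ys, kind)

    boots = _bootstrap_stat(clusters, n_boot, rng, stat)
    boots = boots[np.isfinite(boots)]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return CorrelationResult(estimate=estimate, ci_low=float(lo), ci_high=float(hi),
                             kind=kind, n_boot=n_boot, n_clusters=len(clusters))


@dataclass(frozen=True)
class CorrelationComparison:
    difference: float          # corr(xa, y) - corr(xb, y)
    ci_low: float
    ci_high: float
    p_value: float
    kind: str


def compare_correlations(xa: Sequence[float], xb: Sequence[float], y: Sequence[float],
                         participant_ids: Sequence, kind: str = "pearson",
                         n_boot: int = 2000, seed: int = DEFAULT_SEED,
                         ci: float = 0.95) -> CorrelationComparison:
    """Percentile-bootstrap comparison of two correlations with a common outcome.

    Tests corr(xa, y) − corr(xb, y) on the same eyes, resampling
    participants; swapping ``xa`` and ``xb`` negates the difference and
    leaves the p-value unchanged.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    y = np.asarray(y, dtype=float)
    pid = np.asarray(participant_ids)
    if not (xa.shape == xb.shape == y.shape == pid.shape):
        raise ValueError("inputs must align")
    diff = _corr(xa, y, kind) - _corr(xb, y, kind)
    clusters = _cluster_indices(pid)
    rng = np.random.default_rng(seed)

    def stat(idx: np.ndarray) -> float:
        if np.ptp(y[idx]) == 0 or np.ptp(xa[idx]) == 0 or np.ptp(xb[idx]) == 0:
            return np.nan
        return _corr(xa[idx], y[idx], kind) - _corr(xb[idx], y[idx], kind)

    boots = _bootstrap_stat(clusters, n_boot, rng, stat)
    boots = boots[np.isfinite(boots)]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    p_below = float(np.mean(boots <= 0.0))
    p_above = float(np.mean(boots >= 0.0))
    p = min(1.0, 2.0 * min(p_below, p_above))
    return CorrelationComparison(difference=float(diff), ci_low=float(lo),
                                 ci_high=float(hi), p_value=p, kind=kind)


@dataclass(frozen=True)
class RocResult:
    aroc: float
    sensitivity95: float
    sensitivity99: float
    n_cases: int
    n_controls: int


def aroc_sensitivity(case_values: Sequence[float], control_values: Sequence[float],
                     cutoffs: DiagnosticCutoffs | None = None) -> RocResult:
    """AROC and sensitivity at the fixed-specificity cutoffs.

    Polarity: lower value = more diseased. AROC equals the Mann–Whitney
    probability that a random case scores below a random control, with half
    credit for ties. Sensitivities are the case fractions below each cutoff
    (NaN if no cutoffs are supplied).
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size < 5 or controls.size < 5:
        raise ValueError("need at least 5 eyes per group")
    labels = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    scores = -np.concatenate([cases, controls])   # higher score = more diseased
    aroc = float(roc_auc_score(labels, scores))
    if cutoffs is None:
        s95 = s99 = float("nan")
    else:
        s95 = float(np.mean(cases < cutoffs.cutoff95))
        s99 = float(np.mean(cases < cutoffs.cutoff99))
    return RocResult(aroc=aroc, sensitivity95=s95, sensitivity99=s99,
                     n_cases=cases.size, n_controls=controls.size)


def mcnemar_sensitivity(flags_a: Sequence[bool], flags_b: Sequence[bool]) -> float:
    """McNemar exact p-value for paired abnormality flags of two parameters."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must align")
    table = np.array([
        [np.sum(a & b), np.sum(a & ~b)],
        [np.sum(~a & b), np.sum(~a & ~b)],
    ])
    return float(_sm_mcnemar(table, exact=True).pvalue)
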