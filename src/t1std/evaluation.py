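"""Cohort statistics, ROC analysis and intra-subject progression.

After standardisation, cohorts (healthy, HCM, AMY) are compared with a
normality-routed test pair (t-test + ANOVA if every cohort passes
Shapiro-Wilk, otherwise Mann-Whitney-U + Kruskal-Wallis; a difference
counts as significant only if both the pairwise and the omnibus test reach
alpha). Diagnostic separability is quantified by ROC analysis with the
Youden-optimal threshold; evidence of discrimination is assumed when
sensitivity + specificity reaches 150% or more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .selection import cov

EVIDENCE_THRESHOLD = 150.0  # percent, sensitivity + specificity


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    cov: float
    ci_low: float
    ci_high: float


@dataclass
class RocResult:
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    auc: float
    evidence: bool

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "evidence": self.evidence,
        }


@dataclass
class CohortComparison:
    route: str                       # "parametric" | "nonparametric"
    pairwise_p: dict                 # (label_a, label_b) -> p
    omnibus_p: float
    significant: dict                # (label_a, label_b) -> bool
    alpha: float


def summarise(values, confidence: float = 0.95) -> SummaryStats:
    """Mean, sample SD, COV and the two-sided t-based CI of the mean."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ConfigurationError("summarise needs at least two values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    half = stats.t.ppf(0.5 + confidence / 2, df=v.size - 1) * sd / np.sqrt(v.size)
    return SummaryStats(
        n=int(v.size), mean=mean, sd=sd, cov=cov(v),
        ci_low=mean - half, ci_high=mean + half,
    )


def compare_cohorts(groups: dict, alpha: float = 0.05) -> CohortComparison:
    """Route-selected pairwise + omnibus comparison of labelled cohorts.

    All groups normal by Shapiro-Wilk (p > alpha) -> independent t-test and
    one-way ANOVA; otherwise Mann-Whitney-U and Kruskal-Wallis. A pair is
    significant only if both its pairwise p and the omnibus p are <= alpha.
    Constant groups (normality test undefined) force the nonparametric
    route with a warning.
    """
    if len(groups) < 2:
        raise ConfigurationError("need at least two cohorts")
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in groups.items()}
    for label, v in arrays.items():
        if v.size < 3:
            raise ConfigurationError(f"cohort {label!r} has fewer than 3 values")

    parametric = True
    for label, v in arrays.items():
        if np.ptp(v) == 0:
            warnings.warn(
                f"cohort {label!r} is constant; normality undefined, "
                f"using nonparametric tests", stacklevel=2,
            )
            parametric = False
            break
        if stats.shapiro(v).pvalue <= alpha:
            parametric = False

    labels = list(arrays)
    if parametric:
        omnibus = float(stats.f_oneway(*arrays.values()).pvalue)
    else:
        try:
            omnibus = float(stats.kruskal(*arrays.values()).pvalue)
        except ValueError:  # all values identical across groups
            omnibus = 1.0

    pairwise, significant = {}, {}
    for a, b in combinations(labels, 2):
        va, vb = arrays[a], arrays[b]
        if parametric:
            p = float(stats.ttest_ind(va, vb).pvalue)
        else:
            if np.ptp(np.concatenate([va, vb])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(va, vb,
                                             alternative="two-sided").pvalue)
        pairwise[(a, b)] = p
        significant[(a, b)] = bool(p <= alpha and omnibus <= alpha)

    return CohortComparison(
        route="parametric" if parametric else "nonparametric",
        pairwise_p=pairwise,
        omnibus_p=omnibus,
        significant=significant,
        alpha=alpha,
    )


def roc_analysis(negative, positive) -> RocResult:
    """ROC analysis with a ">= threshold -> positive" rule (disease raises
    T1). Candidate thresholds are the midpoints between consecutive sorted
    pooled unique values plus +-inf; the optimal threshold maximises
    Youden's J = sensitivity + specificity - 100%, ties resolved to the
    lowest threshold. AUC uses the rank (Mann-Whitney) formulation with
    ties counted one half.
    """
    neg = np.asarray(negative, dtype=np.float64)
    pos = np.asarray(positive, dtype=np.float64)
    if neg.size == 0 or pos.size == 0:
        raise ConfigurationError("both ROC samples must be nonempty")

    uniq = np.unique(np.concatenate([neg, pos]))
    candidates = np.concatenate(
        [[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]]
    )
    best = None
    for t in candidates:
        sens = 100.0 * np.mean(pos >= t)
        spec = 100.0 * np.mean(neg < t)
        j = sens + spec - 100.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, threshold, sensitivity, specificity = best

    ranks = stats.rankdata(np.concatenate([neg, pos]))
    r_pos = ranks[neg.size:].sum()
    auc = (r_pos - pos.size * (pos.size + 1) / 2.0) / (neg.size * pos.size)

    return RocResult(
        threshold=float(threshold),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        auc=float(auc),
        evidence=bool(sensitivity + specificity >= EVIDENCE_THRESHOLD),
    )


def intra_subject_progression(results) -> tuple[dict, list]:
    """Per-subject COV of per-map mean T1 before and after standardisation.

    ``results`` is an iterable of StandardisationResult; subjects with a
    single map are excluded and listed in the second return value.
    """
    by_subject: dict[str, list] = {}
    for r in results:
        by_subject.setdefault(r.subject_id or r.map_id, []).append(r)
    progression, excluded = {}, []
    for subject, rs in by_subject.items():
        if len(rs) < 2:
            excluded.append(subject)
            continue
        progression[subject] = (
            cov([r.mean_before for r in rs]),
            cov([r.mean_after for r in rs]),
        )
    return progression, excluded
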