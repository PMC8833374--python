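"""Cohort-level analysis of pathway activity scores.

Contains the normal-range machinery (reference thresholds at mean + 2 SD of
healthy scores, strict-upper classification of abnormally high activity),
the small-sample nonparametric comparisons used throughout (exact
Mann-Whitney U, paired Wilcoxon signed-rank, Pearson correlation), and
matching of a sample's pathway-activity profile against labelled reference
cell-type profiles.

Interpretation rules honoured structurally:

1. Raw log2-odds scores are never pooled across different pathways into one
   statistic (each pathway has its own score range); profile matching first
   standardises each pathway across the pooled reference set.
2. Comparisons are always within one pathway across samples/groups.
3. Scores are kept at full precision; rounding happens only at report
   rendering.
4. A negative log2 odds does not mean an inactive pathway; classification
   speaks only of "abnormally high" relative to a reference range.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import AnalysisError
from .model import ActivityProfile, PathwayScore

logger = logging.getLogger(__name__)

TWO_SIDED, LESS, GREATER = "two_sided", "less", "greater"
_SCIPY_ALT = {TWO_SIDED: "two-sided", LESS: "less", GREATER: "greater"}

ABNORMAL_HIGH, NORMAL = "abnormal_high", "normal"

#: Largest combined sample size for which the exact Mann-Whitney null
#: distribution is enumerated (no ties); beyond it the normal approximation
#: with continuity correction is used.
EXACT_MWU_MAX_N = 20
#: Largest number of nonzero pairs for exact Wilcoxon signed-rank p-values.
EXACT_WILCOXON_MAX_N = 15


@dataclass(frozen=True)
class ReferenceThreshold:
    """Upper bound of the normal range for one pathway: mean + k*SD of
    healthy-reference scores (sample SD, n-1 denominator)."""

    pathway_name: str
    ref_mean: float
    ref_sd: float
    upper: float
    n_ref: int
    k_sd: float = 2.0


@dataclass(frozen=True)
class ComparisonResult:
    method: str  # mann_whitney_exact | mann_whitney_normal_approx |
    #              wilcoxon_signed_rank | pearson
    statistic: float  # U, W, or r
    p_value: float
    alternative: str
    n1: int
    n2: int
    ties_present: bool = False


def normal_threshold(
    ref_scores: Sequence[float], k_sd: float = 2.0, pathway_name: str = ""
) -> ReferenceThreshold:
    """Normal-range upper threshold from healthy reference scores.

    ``upper = mean + k_sd * SD`` with the sample standard deviation
    (n-1 denominator); at least two finite scores are required.
    """
    x = np.asarray(ref_scores, dtype=float)
    if x.size < 2:
        raise AnalysisError(f"need >= 2 reference scores, got {x.size}")
    if not np.isfinite(x).all():
        raise AnalysisError("reference scores must be finite")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return ReferenceThreshold(
        pathway_name=pathway_name,
        ref_mean=mean,
        ref_sd=sd,
        upper=mean + k_sd * sd,
        n_ref=int(x.size),
        k_sd=float(k_sd),
    )


def classify_abnormal(
    scores: Mapping[str, float], thresholds: Mapping[str, ReferenceThreshold]
) -> dict[str, str]:
    """Call each pathway abnormally high iff its score strictly exceeds the
    normal upper threshold; a score exactly at the threshold is normal."""
    missing = [p for p in scores if p not in thresholds]
    if missing:
        raise AnalysisError(f"no threshold for pathways: {sorted(missing)}")
    return {
        p: (ABNORMAL_HIGH if float(s) > thresholds[p].upper else NORMAL)
        for p, s in scores.items()
    }


def _check_alternative(alternative: str) -> str:
    if alternative not in _SCIPY_ALT:
        raise AnalysisError(
            f"alternative must be one of {tuple(_SCIPY_ALT)}, got {alternative!r}"
        )
    return _SCIPY_ALT[alternative]


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = TWO_SIDED,
) -> ComparisonResult:
    """Mann-Whitney U test of group_a against group_b.

    U is the number of (a, b) pairs with a > b (mid-ranks under ties). The
    p-value is exact — from the full null distribution over the
    C(n1+n2, n1) group labelings — when n1+n2 <= 20 and there are no ties;
    otherwise the normal approximation with continuity correction (and tie
    correction) is used.
    """
    scipy_alt = _check_alternative(alternative)
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AnalysisError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    exact = (a.size + b.size) <= EXACT_MWU_MAX_N and not ties
    res = sps.mannwhitneyu(
        a, b, alternative=scipy_alt, method="exact" if exact else "asymptotic"
    )
    return ComparisonResult(
        method="mann_whitney_exact" if exact else "mann_whitney_normal_approx",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alternative=alternative,
        n1=int(a.size),
        n2=int(b.size),
        ties_present=bool(ties),
    )


def wilcoxon_paired(
    x: Sequence[float], y: Sequence[float], alternative: str = TWO_SIDED
) -> ComparisonResult:
    """Paired two-sample Wilcoxon signed-rank test on x - y.

    Zero differences are dropped (their count is logged). W is the sum of
    ranks of positive differences (the smaller of the two rank sums under
    the two-sided alternative). Exact p by enumeration of the 2^n sign
    patterns when n <= 15 nonzero pairs and no tied |differences|; otherwise
    the normal approximation with continuity correction.
    """
    scipy_alt = _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size == 0:
        raise AnalysisError("paired samples must have equal nonzero length")
    d = x - y
    n_zero = int(np.sum(d == 0))
    if n_zero:
        logger.info("wilcoxon_paired: dropping %d zero difference(s)", n_zero)
    d = d[d != 0]
    if d.size == 0:
        logger.warning("wilcoxon_paired: all differences zero; degenerate p = 1")
        return ComparisonResult(
            method="wilcoxon_signed_rank",
            statistic=0.0,
            p_value=1.0,
            alternative=alternative,
            n1=int(x.size),
            n2=int(y.size),
            ties_present=True,
        )
    absd = np.abs(d)
    tied = len(np.unique(absd)) < absd.size
    exact = d.size <= EXACT_WILCOXON_MAX_N and not tied
    res = sps.wilcoxon(
        d,
        alternative=scipy_alt,
        zero_method="wilcox",
        correction=not exact,
        method="exact" if exact else "approx",
    )
    return ComparisonResult(
        method="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        alternative=alternative,
        n1=int(d.size),
        n2=int(d.size),
        ties_present=bool(tied),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> ComparisonResult:
    """Pearson correlation with the two-sided t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise AnalysisError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance in input")
    res = sps.pearsonr(x, y)
    return ComparisonResult(
        method="pearson",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alternative=TWO_SIDED,
        n1=int(x.size),
        n2=int(y.size),
    )


@dataclass(frozen=True)
class ProfileMatch:
    """Best-matching reference cell type for one sample profile."""

    sample_id: str
    reference_label: str
    similarity: float
    ranking: tuple[tuple[str, float], ...]  # (label, similarity), best first


def _as_score_map(profile) -> dict[str, float]:
    if isinstance(profile, ActivityProfile):
        return profile.log2_odds()
    return {p: float(v) for p, v in dict(profile).items()}


def match_profile(
    profile,
    references: Mapping[str, object],
    sample_id: str | None = None,
) -> ProfileMatch:
    """Match a sample's pathway profile to labelled reference profiles.

    Because raw log2-odds are not comparable across pathways (each pathway
    has its own score range), every pathway is first standardised — centred
    and scaled by the pooled reference set's per-pathway mean and SD — and
    similarity is the Pearson correlation of the standardised vectors over
    the shared pathway set. References are ranked by similarity; exact ties
    break by reference label order.

    ``profile`` and each reference may be an :class:`ActivityProfile` or a
    plain pathway -> log2-odds mapping.
    """
    prof = _as_score_map(profile)
    if sample_id is None:
        sample_id = profile.sample_id if isinstance(profile, ActivityProfile) else ""
    refs = {label: _as_score_map(r) for label, r in references.items()}
    if not refs:
        raise AnalysisError("no reference profiles supplied")
    common = [p for p in prof if all(p in r for r in refs.values())]
    if len(common) < 2:
        raise AnalysisError(
            f"need >= 2 pathways shared between profile and references, got {common}"
        )
    # per-pathway standardisation statistics from the pooled reference set
    ref_mat = np.array([[refs[l][p] for p in common] for l in refs], dtype=float)
    mu = ref_mat.mean(axis=0)
    sd = ref_mat.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant-across-references pathway: centre only
    z_prof = (np.array([prof[p] for p in common]) - mu) / sd
    sims: list[tuple[str, float]] = []
    for i, label in enumerate(refs):
        z_ref = (ref_mat[i] - mu) / sd
        if np.ptp(z_prof) == 0 or np.ptp(z_ref) == 0:
            sim = 0.0
        else:
            sim = float(np.corrcoef(z_prof, z_ref)[0, 1])
        sims.append((label, sim))
    ranking = tuple(sorted(sims, key=lambda t: (-t[1], t[0])))
    best_label, best_sim = ranking[0]
    return ProfileMatch(
        sample_id=sample_id,
        reference_label=best_label,
        similarity=best_sim,
        ranking=ranking,
    )


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-adjusted p-values (report transparency only; verdicts in
    this package never use them, mirroring the single-test convention)."""
    m = len(p_values)
    return [min(1.0, float(p) * m) for p in p_values]
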