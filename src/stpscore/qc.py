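"""Per-sample microarray quality control.

A rule engine over a per-sample table of Affymetrix-style quality metrics:
average probe intensity, counts of negative and >16-bit (overflow) values,
poly-A and labelled-cRNA spike-in control flags, GAPDH and ACTB 3'/5'
ratios, centre of intensity, positive/negative border-control means, and an
RNA degradation slope. Samples failing any enabled rule are removed before
analysis. Thresholds follow common Affymetrix guidance (e.g. 3'/5' ratio
<= 3) but every bound is configurable; cohort-relative bounds (mean +/- 3 SD)
are provided for the metrics whose natural scale varies by experiment.

Calculators are included for the metrics derivable from probe-summary
inputs (3'/5' ratios, degradation slope); the remaining metrics are consumed
as precomputed columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCMetrics:
    """One sample's quality-metric panel."""

    sample_id: str
    avg_intensity: float
    n_negative_values: int
    n_overflow_values: int
    polyA_spike_ok: bool
    cRNA_spike_ok: bool
    gapdh_3p5p_ratio: float
    actb_3p5p_ratio: float
    center_of_intensity: float
    pos_border_mean: float
    neg_border_mean: float
    rna_deg_slope: float

    def __post_init__(self) -> None:
        if self.n_negative_values < 0 or self.n_overflow_values < 0:
            raise ConfigError("counts must be >= 0")
        if self.gapdh_3p5p_ratio <= 0 or self.actb_3p5p_ratio <= 0:
            raise ConfigError("3'/5' ratios must be > 0")


METRIC_NAMES = tuple(f.name for f in dc_fields(QCMetrics) if f.name != "sample_id")
BOOLEAN_METRICS = ("polyA_spike_ok", "cRNA_spike_ok")


@dataclass(frozen=True)
class QCRule:
    """Bounds (or required-true) for one metric; ``None`` bound = unchecked."""

    metric: str
    min: float | None = None
    max: float | None = None
    require_true: bool = False
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ConfigError(f"unknown QC metric {self.metric!r}")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ConfigError(
                f"rule {self.metric}: min {self.min} > max {self.max}"
            )

    def passes(self, value) -> bool:
        if self.require_true:
            return bool(value)
        v = float(value)
        if self.min is not None and v < self.min:
            return False
        if self.max is not None and v > self.max:
            return False
        return True

    def describe(self) -> str:
        if self.require_true:
            return f"{self.metric} must be true"
        parts = []
        if self.min is not None:
            parts.append(f">= {self.min:g}")
        if self.max is not None:
            parts.append(f"<= {self.max:g}")
        return f"{self.metric} must be " + " and ".join(parts)


@dataclass(frozen=True)
class QCRuleSet:
    rules: tuple[QCRule, ...]

    def __post_init__(self) -> None:
        names = [r.metric for r in self.rules]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate rules for a metric")

    def enabled_rules(self) -> tuple[QCRule, ...]:
        return tuple(r for r in self.rules if r.enabled)


#: Maximum representable value of a 16-bit scanner pixel.
OVERFLOW_LIMIT = 65535

# Fixed default bounds (Affymetrix guidance); shared with the QC-table simulator.
DEFAULT_FIXED_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "gapdh_3p5p_ratio": (None, 3.0),
    "actb_3p5p_ratio": (None, 3.0),
    "n_negative_values": (None, 0.0),
    "n_overflow_values": (None, 0.0),
    "rna_deg_slope": (-1.0, 4.0),
}
# Typical generating ranges for the cohort-relative metrics, used by the
# simulator and as fall-back fixed bounds.
DEFAULT_COHORT_BOUNDS: dict[str, tuple[float, float]] = {
    "avg_intensity": (90.0, 210.0),
    "center_of_intensity": (0.35, 0.65),
    "pos_border_mean": (110.0, 290.0),
    "neg_border_mean": (15.0, 105.0),
}


def default_rules() -> QCRuleSet:
    """Default rule set: fixed Affymetrix-guidance bounds for every metric."""
    rules = [QCRule(m, require_true=True) for m in BOOLEAN_METRICS]
    for m, (lo, hi) in DEFAULT_FIXED_BOUNDS.items():
        rules.append(QCRule(m, min=lo, max=hi))
    for m, (lo, hi) in DEFAULT_COHORT_BOUNDS.items():
        rules.append(QCRule(m, min=lo, max=hi))
    return QCRuleSet(tuple(rules))


def cohort_relative_rules(
    metrics: Sequence[QCMetrics], k_sd: float = 3.0
) -> QCRuleSet:
    """Default rules with mean +/- k_sd*SD cohort bounds for scale-dependent metrics.

    Applies to average intensity, centre of intensity and the border-control
    means, whose natural scale varies between experiments.
    """
    rules = [QCRule(m, require_true=True) for m in BOOLEAN_METRICS]
    for m, (lo, hi) in DEFAULT_FIXED_BOUNDS.items():
        rules.append(QCRule(m, min=lo, max=hi))
    for m in DEFAULT_COHORT_BOUNDS:
        vals = np.array([getattr(x, m) for x in metrics], dtype=float)
        mu, sd = float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rules.append(QCRule(m, min=mu - k_sd * sd, max=mu + k_sd * sd))
    return QCRuleSet(tuple(rules))


def three_prime_ratio(probe_intensities_3p: float, probe_intensities_5p: float) -> float:
    """3'/5' intensity ratio of a housekeeping control probeset (GAPDH, ACTB).

    Ratios well above 1 indicate RNA degradation or inefficient labelling
    (the 3' end survives oligo-dT priming; guidance flags ratios > 3).
    """
    if probe_intensities_3p <= 0 or probe_intensities_5p <= 0:
        raise ConfigError("probe intensities must be > 0")
    return float(probe_intensities_3p) / float(probe_intensities_5p)


def rna_degradation_slope(mean_intensity_by_probe_position: Sequence[float]) -> float:
    """OLS slope of mean probe intensity against 5'->3' probe-position index.

    Degraded RNA yields systematically higher intensity toward the 3' end,
    i.e., a large positive slope.
    """
    y = np.asarray(mean_intensity_by_probe_position, dtype=float)
    if y.size < 3:
        raise ConfigError(f"need >= 3 probe positions, got {y.size}")
    x = np.arange(y.size, dtype=float)
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    verdicts: Mapping[str, bool]  # rule metric -> pass
    overall_pass: bool
    failure_reasons: tuple[str, ...]


def evaluate_qc(metrics: QCMetrics, rules: QCRuleSet) -> QCReport:
    """Evaluate one sample against a rule set; pure and order-independent."""
    verdicts: dict[str, bool] = {}
    reasons: list[str] = []
    for rule in rules.enabled_rules():
        value = getattr(metrics, rule.metric)
        ok = rule.passes(value)
        verdicts[rule.metric] = ok
        if not ok:
            reasons.append(f"{rule.describe()} (observed {value!r})")
    reasons.sort()  # independent of rule order
    return QCReport(
        sample_id=metrics.sample_id,
        verdicts=verdicts,
        overall_pass=all(verdicts.values()),
        failure_reasons=tuple(reasons),
    )


def filter_cohort(
    cohort: ExpressionMatrix, reports: Sequence[QCReport]
) -> ExpressionMatrix:
    """Drop QC-failing samples, preserving the order of survivors."""
    by_id = {r.sample_id: r for r in reports}
    missing = [s for s in cohort.sample_ids if s not in by_id]
    if missing:
        raise ConfigError(f"no QC report for samples: {missing}")
    keep = [s for s in cohort.sample_ids if by_id[s].overall_pass]
    removed = [s for s in cohort.sample_ids if not by_id[s].overall_pass]
    if removed:
        logger.info("QC removed %d sample(s): %s", len(removed), removed)
    return cohort.subset_samples(keep)
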