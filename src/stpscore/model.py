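"""Calibrate-then-freeze Bayesian pathway-activity scoring.

The scoring model is a two-layer Bayesian network: a hidden binary pathway
state (the transcription factor active or not) and, conditionally independent
given that state, one binary evidence node per target gene ("expression above
the gene's discretization cutoff"). Calibration on a labelled training cohort
of a single cell type estimates, per gene, a discretization cutoff (the
training median) and pseudocount-smoothed conditional probabilities of high
expression given the active and inactive states. The calibrated model is
frozen: applying it to new samples never updates its parameters.

Scoring a sample multiplies the prior odds of activity by each observed
gene's likelihood ratio and reports both the posterior probability P and the
log2 odds, log2(P / (1 - P)), the pathway-activity unit used throughout the
package. Down-regulated target genes need no special casing: their calibrated
P(high | active) simply comes out below P(high | inactive), flipping the
likelihood ratio.

PI3K pathway activity is not scored directly: it is inferred inversely from
the measured FOXO transcription-factor activity, a relationship that is only
valid in the absence of cellular oxidative stress (oxidative stress activates
FOXO independently of PI3K). FOXO is therefore always reported as a FOXO
activity, never relabelled as a PI3K score.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CalibrationError, ConfigError, ScoringError
from .expression import ExpressionMatrix
from .gene_sets import TargetGeneSet

logger = logging.getLogger(__name__)

#: Hard clamp on reported log2-odds; prevents +/-inf from extreme products.
LOG2_ODDS_CLAMP = 60.0

ACTIVE, INACTIVE = "active", "inactive"


@dataclass(frozen=True)
class GeneParams:
    """Per-gene frozen parameters: cutoff and conditional probabilities."""

    direction: str
    cutoff: float
    p_high_given_active: float
    p_high_given_inactive: float

    def __post_init__(self) -> None:
        for name in ("p_high_given_active", "p_high_given_inactive"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ConfigError(f"{name} must lie strictly in (0,1), got {p}")


@dataclass(frozen=True)
class FrozenPathwayModel:
    """A calibrated, immutable pathway scoring model.

    ``gene_params`` preserves the order of the calibrating gene set. The
    dataclass is frozen and the mapping is wrapped read-only, so a model can
    never drift after calibration.
    """

    pathway_name: str
    prior_active: float
    gene_params: Mapping[str, GeneParams]
    frozen: bool = True
    calibration_meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_active < 1.0):
            raise ConfigError(
                f"prior_active must lie strictly in (0,1), got {self.prior_active}"
            )
        if len(self.gene_params) < 1:
            raise ConfigError(f"model {self.pathway_name!r} has no genes")
        object.__setattr__(self, "gene_params", MappingProxyType(dict(self.gene_params)))
        object.__setattr__(
            self, "calibration_meta", MappingProxyType(dict(self.calibration_meta))
        )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.gene_params)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.pathway_name.encode())
        h.update(repr(self.prior_active).encode())
        for g, gp in self.gene_params.items():
            h.update(
                f"{g}|{gp.direction}|{gp.cutoff!r}|{gp.p_high_given_active!r}|"
                f"{gp.p_high_given_inactive!r}".encode()
            )
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class PathwayScore:
    """Posterior activity of one pathway in one sample."""

    sample_id: str
    pathway_name: str
    prob_active: float
    log2_odds: float
    n_genes_used: int
    missing_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ActivityProfile:
    """Per-sample map of pathway name -> PathwayScore, plus sample annotations.

    FOXO appears under its own name: it is a transcription-factor activity
    readout and is never relabelled as a PI3K pathway score.
    """

    sample_id: str
    scores: Mapping[str, PathwayScore]
    annotations: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", MappingProxyType(dict(self.scores)))
        object.__setattr__(self, "annotations", MappingProxyType(dict(self.annotations)))

    def log2_odds(self) -> dict[str, float]:
        return {p: s.log2_odds for p, s in self.scores.items()}


def _prob_from_log2_odds(lo: float) -> float:
    # 1 / (1 + 2^-lo); saturates to 0/1 in float64 beyond |lo| ~ 50
    return 1.0 / (1.0 + 2.0 ** (-lo))


def calibrate_model(
    train: ExpressionMatrix,
    labels: Mapping[str, str],
    gene_set: TargetGeneSet,
    prior_active: float = 0.5,
    pseudocount: float = 1.0,
) -> FrozenPathwayModel:
    """Calibrate and freeze a pathway model on a labelled training cohort.

    Parameters
    ----------
    train
        Training expression matrix (log2 scale), one cell type.
    labels
        sample_id -> ``"active"`` / ``"inactive"``; both classes need >= 2
        samples.
    gene_set
        Target genes with expected regulation directions. Genes absent from
        ``train`` or with degenerate (constant) training values are dropped
        with a warning.
    prior_active
        Prior probability of the active state, frozen into the model.
    pseudocount
        Laplace smoothing count; keeps every conditional probability strictly
        inside (0,1) so no single gene can produce infinite odds.
    """
    if pseudocount <= 0:
        raise ConfigError(f"pseudocount must be positive, got {pseudocount}")
    bad = {s: l for s, l in labels.items() if l not in (ACTIVE, INACTIVE)}
    if bad:
        raise CalibrationError(f"labels must be 'active'/'inactive', got {bad}")
    unknown = [s for s in labels if s not in train.values.columns]
    if unknown:
        raise CalibrationError(f"labelled samples missing from training data: {unknown}")
    active_ids = [s for s in train.sample_ids if labels.get(s) == ACTIVE]
    inactive_ids = [s for s in train.sample_ids if labels.get(s) == INACTIVE]
    if len(active_ids) < 2 or len(inactive_ids) < 2:
        raise CalibrationError(
            f"need >= 2 samples per class, got {len(active_ids)} active / "
            f"{len(inactive_ids)} inactive"
        )

    train_ids = active_ids + inactive_ids
    params: dict[str, GeneParams] = {}
    for gene in gene_set.genes:
        g = gene.gene_id
        if g not in train.values.index:
            logger.warning(
                "gene %s not in training matrix; dropped from %s model",
                g, gene_set.pathway_name,
            )
            continue
        vals = train.values.loc[g, train_ids].to_numpy(dtype=float)
        cutoff = float(np.median(vals))
        if np.ptp(vals) == 0.0:
            logger.warning(
                "gene %s has constant training values (degenerate cutoff); "
                "dropped from %s model", g, gene_set.pathway_name,
            )
            continue
        act = train.values.loc[g, active_ids].to_numpy(dtype=float)
        inact = train.values.loc[g, inactive_ids].to_numpy(dtype=float)
        p_hi_act = (float(np.sum(act > cutoff)) + pseudocount) / (
            len(act) + 2.0 * pseudocount
        )
        p_hi_inact = (float(np.sum(inact > cutoff)) + pseudocount) / (
            len(inact) + 2.0 * pseudocount
        )
        params[g] = GeneParams(
            direction=gene.direction,
            cutoff=cutoff,
            p_high_given_active=p_hi_act,
            p_high_given_inactive=p_hi_inact,
        )
    if not params:
        raise CalibrationError(
            f"no usable genes for pathway {gene_set.pathway_name!r} after dropping "
            "missing/degenerate genes"
        )
    model = FrozenPathwayModel(
        pathway_name=gene_set.pathway_name,
        prior_active=float(prior_active),
        gene_params=params,
        frozen=True,
        calibration_meta={
            "n_active": len(active_ids),
            "n_inactive": len(inactive_ids),
            "pseudocount": float(pseudocount),
        },
    )
    meta = dict(model.calibration_meta)
    meta["hash"] = model.content_hash()
    object.__setattr__(model, "calibration_meta", MappingProxyType(meta))
    return model


def score_sample(model: FrozenPathwayModel, sample: Mapping[str, float],
                 sample_id: str = "") -> PathwayScore:
    """Score one sample (gene -> log2 value map) with a frozen model.

    Evidence per gene is binary: value above the frozen cutoff. Genes missing
    from the sample contribute a likelihood ratio of 1 and are listed in
    ``missing_genes``; a sample sharing no genes at all with the model is a
    scoring error rather than a silent prior return.
    """
    if not model.frozen:
        raise ScoringError(f"model {model.pathway_name!r} is not frozen")
    lo = math.log2(model.prior_active) - math.log2(1.0 - model.prior_active)
    missing: list[str] = []
    n_used = 0
    for g, gp in model.gene_params.items():
        if g not in sample:
            missing.append(g)
            continue
        n_used += 1
        if float(sample[g]) > gp.cutoff:
            num, den = gp.p_high_given_active, gp.p_high_given_inactive
        else:
            num, den = 1.0 - gp.p_high_given_active, 1.0 - gp.p_high_given_inactive
        lo += math.log2(num) - math.log2(den)
    if n_used == 0:
        raise ScoringError(
            f"sample {sample_id!r} shares no genes with model {model.pathway_name!r}"
        )
    lo = min(max(lo, -LOG2_ODDS_CLAMP), LOG2_ODDS_CLAMP)
    return PathwayScore(
        sample_id=sample_id,
        pathway_name=model.pathway_name,
        prob_active=_prob_from_log2_odds(lo),
        log2_odds=lo,
        n_genes_used=n_used,
        missing_genes=tuple(missing),
    )


def score_cohort(
    models: Sequence[FrozenPathwayModel], cohort: ExpressionMatrix
) -> list[ActivityProfile]:
    """Score every sample of a cohort with a set of frozen pathway models.

    One ActivityProfile per sample, in cohort column order. Each sample's
    scores depend only on its own column: re-scoring after adding unrelated
    samples leaves existing scores bit-identical.
    """
    if len(models) < 1:
        raise ConfigError("need at least one model")
    if cohort.n_samples < 1:
        raise ConfigError("cohort has no samples")
    names = [m.pathway_name for m in models]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"duplicate pathway names across models: {dupes}")
    profiles = []
    for sid in cohort.sample_ids:
        sample = cohort.sample_values(sid)
        scores = {m.pathway_name: score_sample(m, sample, sample_id=sid) for m in models}
        ann = cohort.annotations.loc[sid].to_dict() if len(cohort.annotations.columns) else {}
        profiles.append(ActivityProfile(sample_id=sid, scores=scores, annotations=ann))
    return profiles


PI3K_LOW, PI3K_HIGH, PI3K_INDETERMINATE = "pi3k_low", "pi3k_high", "indeterminate"


def infer_pi3k_from_foxo(
    foxo_score: float, reference: float, oxidative_stress: bool = False
) -> str:
    """Qualitative PI3K pathway call by inverse inference from FOXO activity.

    Relative to a reference FOXO score (e.g., a comparison sample), a higher
    FOXO activity implies lower PI3K pathway activity and vice versa. Under
    cellular oxidative stress FOXO is activated independently of PI3K and the
    inversion is invalid, so the call is ``indeterminate``. A tie is also
    ``indeterminate``.
    """
    if oxidative_stress:
        return PI3K_INDETERMINATE
    foxo_score, reference = float(foxo_score), float(reference)
    if foxo_score > reference:
        return PI3K_LOW
    if foxo_score < reference:
        return PI3K_HIGH
    return PI3K_INDETERMINATE
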