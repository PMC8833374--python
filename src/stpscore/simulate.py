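"""Synthetic cohorts with planted pathway-activation ground truth.

The generator emulates the structure of CD4+ T-cell expression studies:
scenarios (resting, activated, Th1, Th2, resting/suppressive Treg,
supernatant-treated activated cells, and matched patient blood / lymph-node /
tumour-infiltrate samples) each carry a per-pathway activation level
``a`` in [0, 1]. A target gene g of pathway P with regulation direction d
(+1 up, -1 down) in a sample with activation a is drawn as

    value_g = mu_g + d * effect_size * a + eps,   eps ~ N(0, noise_sd^2)

with a per-gene baseline mu_g drawn once per cohort from N(7, 1) log2 units;
background genes receive baseline plus noise only. This linear-in-activation
Gaussian shift is the simplest generative structure whose planted truth the
Bayesian score should recover, with the effect size and noise as explicit
knobs. Randomness uses numpy's default PCG64 generator seeded once per
cohort; draws occur in a fixed order (baselines first, then per sample:
mixture fraction if any, then the noise vector), so a given spec + seed is
bit-reproducible.

Patient scenarios are mixtures: each patient sample draws a regulatory
T-cell fraction and interpolates its activation vector between a base state
and the suppressive iTreg state — a small fraction in blood, a high fraction
in tumour infiltrate — so blood shows attenuated and TIL pronounced iTreg
signatures. The fractions are illustrative, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression import ExpressionMatrix
from .gene_sets import TargetGeneSet, make_gene_set
from .model import FrozenPathwayModel, calibrate_model
from .qc import QCMetrics

#: The six pathway-activity readouts (FOXO is the transcription-factor
#: readout from which PI3K activity is inversely inferred).
PATHWAYS = ("FOXO", "NFkB", "JAK-STAT1/2", "JAK-STAT3", "TGFb", "Notch")

_GENE_PREFIX = {
    "FOXO": "FOXO",
    "NFkB": "NFKB",
    "JAK-STAT1/2": "STAT12",
    "JAK-STAT3": "STAT3",
    "TGFb": "TGFB",
    "Notch": "NOTCH",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulated cell-state group with planted per-pathway activation."""

    label: str
    activation: Mapping[str, float]  # pathway -> a in [0, 1]
    n_samples: int
    effect_size: float = 2.0  # log2 units at a = 1
    noise_sd: float = 0.5  # log2 units; 0 gives the exact noise-free limit
    mix_target: Mapping[str, float] | None = None  # e.g. iTreg activation
    mix_fraction: tuple[float, float] | None = None  # per-sample U(lo, hi)

    def __post_init__(self) -> None:
        for p, a in self.activation.items():
            if not (0.0 <= a <= 1.0):
                raise ConfigError(f"{self.label}: activation[{p}] = {a} outside [0,1]")
        if self.effect_size <= 0:
            raise ConfigError(f"{self.label}: effect_size must be > 0")
        if self.noise_sd < 0:
            raise ConfigError(f"{self.label}: noise_sd must be >= 0")
        if self.n_samples < 1:
            raise ConfigError(f"{self.label}: n_samples must be >= 1")
        if (self.mix_target is None) != (self.mix_fraction is None):
            raise ConfigError(f"{self.label}: mix_target and mix_fraction go together")
        if self.mix_fraction is not None:
            lo, hi = self.mix_fraction
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"{self.label}: mix_fraction must satisfy 0<=lo<=hi<=1")


@dataclass
class SimulationTruth:
    """Planted per-sample, per-pathway activation; recovery target for tests."""

    activation: pd.DataFrame  # samples x pathways
    labels: pd.Series  # sample -> scenario label
    seed: int


def default_gene_sets(
    n_genes: int = 25, n_down: int = 5, pathways: Sequence[str] = PATHWAYS
) -> list[TargetGeneSet]:
    """Synthetic target-gene sets, ``n_genes`` per pathway with ``n_down``
    down-regulated members (real target-gene lists are proprietary; these
    stand in for testing the machinery)."""
    if not (0 <= n_down < n_genes):
        raise ConfigError("need 0 <= n_down < n_genes")
    sets = []
    for p in pathways:
        prefix = _GENE_PREFIX.get(p, p.replace("/", "").replace("-", ""))
        ids = [f"{prefix}_TG{i + 1:02d}" for i in range(n_genes)]
        sets.append(
            make_gene_set(p, up=ids[: n_genes - n_down], down=ids[n_genes - n_down:],
                          source="synthetic")
        )
    return sets


def simulate_cohort(
    specs: Sequence[ScenarioSpec],
    gene_sets: Sequence[TargetGeneSet],
    n_background_genes: int = 100,
    seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a log2 expression cohort with planted activation truth.

    Gene sets must be pairwise disjoint (cross-pathway transcriptional
    crosstalk is out of scope) and disjoint from the generated background
    gene ids.
    """
    seen: dict[str, str] = {}
    for gs in gene_sets:
        for g in gs.gene_ids:
            if g in seen:
                raise ConfigError(
                    f"gene {g} appears in both {seen[g]!r} and {gs.pathway_name!r}"
                )
            seen[g] = gs.pathway_name
    background = [f"BG{i + 1:04d}" for i in range(n_background_genes)]
    clash = sorted(set(background) & set(seen))
    if clash:
        raise ConfigError(f"background gene ids clash with gene sets: {clash}")

    gene_ids = [g for gs in gene_sets for g in gs.gene_ids] + background
    # signed effect direction per gene (0 for background)
    direction = np.zeros(len(gene_ids))
    pathway_of: list[str | None] = [None] * len(gene_ids)
    pos = 0
    for gs in gene_sets:
        for gene in gs.genes:
            direction[pos] = 1.0 if gene.direction == "up" else -1.0
            pathway_of[pos] = gs.pathway_name
            pos += 1

    universe = [gs.pathway_name for gs in gene_sets]
    for spec in specs:
        for p in spec.activation:
            if p not in universe and p not in PATHWAYS:
                raise ConfigError(f"{spec.label}: unknown pathway {p!r}")

    rng = np.random.default_rng(seed)
    mu = rng.normal(baseline_mean, baseline_sd, size=len(gene_ids))

    columns: dict[str, np.ndarray] = {}
    truth_rows: list[dict[str, float]] = []
    labels: dict[str, str] = {}
    for spec in specs:
        for i in range(spec.n_samples):
            sid = f"{spec.label}_s{i + 1:02d}"
            if sid in columns:
                raise ConfigError(f"duplicate sample id {sid} (reused scenario label?)")
            a = {p: float(spec.activation.get(p, 0.0)) for p in universe}
            if spec.mix_target is not None:
                f = float(rng.uniform(*spec.mix_fraction))
                tgt = {p: float(spec.mix_target.get(p, 0.0)) for p in a}
                a = {p: (1.0 - f) * a[p] + f * tgt[p] for p in a}
            shift = np.array(
                [a.get(pw, 0.0) if pw is not None else 0.0 for pw in pathway_of]
            )
            eps = (
                rng.normal(0.0, spec.noise_sd, size=len(gene_ids))
                if spec.noise_sd > 0
                else np.zeros(len(gene_ids))
            )
            columns[sid] = mu + direction * spec.effect_size * shift + eps
            truth_rows.append(a)
            labels[sid] = spec.label

    values = pd.DataFrame(columns, index=gene_ids)
    ann = pd.DataFrame({"scenario": pd.Series(labels)})
    truth = SimulationTruth(
        activation=pd.DataFrame(truth_rows, index=list(columns)),
        labels=pd.Series(labels, name="scenario"),
        seed=int(seed),
    )
    return ExpressionMatrix(values=values, annotations=ann), truth


# Per-pathway activation levels of the preset cell states. Orderings encode
# the qualitative anchors the package must reproduce after scoring:
# activation raises NFkB/JAK-STAT1/2/JAK-STAT3 and lowers FOXO and TGFb;
# Th1 exceeds Th2 on NFkB and JAK-STAT1/2 while Th2 exceeds Th1 on FOXO;
# the suppressive iTreg state raises NFkB, JAK-STAT3, TGFb, Notch and FOXO
# and lowers JAK-STAT1/2 relative to activated effectors; resting Treg carry
# higher Notch than conventional cells; cancer supernatant partially reverts
# the activated profile while strongly raising TGFb.
PRESET_ACTIVATION: dict[str, dict[str, float]] = {
    "resting":           {"FOXO": 0.8, "NFkB": 0.1, "JAK-STAT1/2": 0.2,
                          "JAK-STAT3": 0.2, "TGFb": 0.3, "Notch": 0.2},
    "activated":         {"FOXO": 0.2, "NFkB": 0.7, "JAK-STAT1/2": 0.5,
                          "JAK-STAT3": 0.7, "TGFb": 0.1, "Notch": 0.2},
    "Th1":               {"FOXO": 0.2, "NFkB": 0.9, "JAK-STAT1/2": 0.9,
                          "JAK-STAT3": 0.7, "TGFb": 0.1, "Notch": 0.2},
    "Th2":               {"FOXO": 0.5, "NFkB": 0.3, "JAK-STAT1/2": 0.2,
                          "JAK-STAT3": 0.7, "TGFb": 0.1, "Notch": 0.2},
    "Treg_resting":      {"FOXO": 0.5, "NFkB": 0.2, "JAK-STAT1/2": 0.4,
                          "JAK-STAT3": 0.3, "TGFb": 0.2, "Notch": 0.6},
    "iTreg":             {"FOXO": 0.7, "NFkB": 0.9, "JAK-STAT1/2": 0.2,
                          "JAK-STAT3": 0.9, "TGFb": 0.9, "Notch": 0.9},
    "activated_plus_SN": {"FOXO": 0.9, "NFkB": 0.2, "JAK-STAT1/2": 0.2,
                          "JAK-STAT3": 0.4, "TGFb": 0.7, "Notch": 0.2},
}

#: Qualitative anchors: (pathway, higher-activity label, lower-activity label).
PRESET_ANCHORS: tuple[tuple[str, str, str], ...] = (
    # CD3/CD28 activation of naive cells
    ("NFkB", "activated", "resting"),
    ("JAK-STAT1/2", "activated", "resting"),
    ("JAK-STAT3", "activated", "resting"),
    ("FOXO", "resting", "activated"),
    ("TGFb", "resting", "activated"),
    # Th1 vs Th2 polarisation
    ("NFkB", "Th1", "Th2"),
    ("JAK-STAT1/2", "Th1", "Th2"),
    ("FOXO", "Th2", "Th1"),
    # suppressive (induced) Treg state vs activated effectors
    ("NFkB", "iTreg", "activated"),
    ("JAK-STAT3", "iTreg", "activated"),
    ("TGFb", "iTreg", "activated"),
    ("Notch", "iTreg", "activated"),
    ("FOXO", "iTreg", "activated"),
    ("JAK-STAT1/2", "activated", "iTreg"),
    # Notch marks Treg states generally
    ("Notch", "Treg_resting", "resting"),
    ("Notch", "Treg_resting", "activated"),
    # cancer-supernatant treatment of activated cells
    ("NFkB", "activated", "activated_plus_SN"),
    ("JAK-STAT1/2", "activated", "activated_plus_SN"),
    ("JAK-STAT3", "activated", "activated_plus_SN"),
    ("TGFb", "activated_plus_SN", "activated"),
    ("FOXO", "activated_plus_SN", "activated"),
    ("JAK-STAT3", "activated_plus_SN", "resting"),
)


def scenario_presets(
    n_replicates: int = 6,
    n_patients: int = 10,
    n_healthy: int = 4,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
) -> list[ScenarioSpec]:
    """Preset scenario list covering the study's cell states and cohorts.

    In-vitro states get ``n_replicates`` samples each; the matched patient
    compartments (blood, lymph node, tumour infiltrate) get ``n_patients``
    and the healthy-donor blood reference ``n_healthy``, mirroring a
    10-patient / 4-donor clinical layout.
    """
    specs = [
        ScenarioSpec(label, dict(act), n_replicates, effect_size, noise_sd)
        for label, act in PRESET_ACTIVATION.items()
    ]
    itreg = PRESET_ACTIVATION["iTreg"]
    specs.append(
        ScenarioSpec("healthy_blood", dict(PRESET_ACTIVATION["resting"]),
                     n_healthy, effect_size, noise_sd)
    )
    for label, base, frac in (
        ("patient_blood", "resting", (0.15, 0.35)),
        ("patient_LN", "resting", (0.30, 0.50)),
        ("patient_TIL", "activated", (0.60, 0.90)),
    ):
        specs.append(
            ScenarioSpec(
                label,
                dict(PRESET_ACTIVATION[base]),
                n_patients,
                effect_size,
                noise_sd,
                mix_target=dict(itreg),
                mix_fraction=frac,
            )
        )
    return specs


def calibration_cohort(
    gene_set: TargetGeneSet,
    n_per_class: int = 20,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """A fully-on / fully-off two-class training cohort for one pathway.

    Mirrors the calibrate-on-one-cell-type-then-freeze protocol: models are
    calibrated once on a dedicated cohort and applied frozen everywhere else.
    """
    p = gene_set.pathway_name
    specs = [
        ScenarioSpec("calib_active", {p: 1.0}, n_per_class, effect_size, noise_sd),
        ScenarioSpec("calib_inactive", {p: 0.0}, n_per_class, effect_size, noise_sd),
    ]
    cohort, _ = simulate_cohort(specs, [gene_set], n_background_genes=0, seed=seed)
    labels = {
        s: ("active" if s.startswith("calib_active") else "inactive")
        for s in cohort.sample_ids
    }
    return cohort, labels


def calibrate_frozen_models(
    gene_sets: Sequence[TargetGeneSet],
    seed: int = 0,
    n_per_class: int = 20,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    prior_active: float = 0.5,
    pseudocount: float = 1.0,
) -> list[FrozenPathwayModel]:
    """Calibrate one frozen model per pathway on dedicated training cohorts."""
    models = []
    for k, gs in enumerate(gene_sets):
        sub_seed = (int(seed) * 97 + k) % (2**31)
        cohort, labels = calibration_cohort(
            gs, n_per_class=n_per_class, effect_size=effect_size,
            noise_sd=noise_sd, seed=sub_seed,
        )
        models.append(
            calibrate_model(cohort, labels, gs, prior_active=prior_active,
                            pseudocount=pseudocount)
        )
    return models


# Metrics a planted QC failure may land on (fixed-bound metrics only, so
# cohort-relative bounds computed from the table stay uncontaminated) and
# the far-out value planted, >= 5 bound-widths beyond the default bound.
_QC_FAILURE_VALUES: dict[str, object] = {
    "gapdh_3p5p_ratio": 18.0,
    "actb_3p5p_ratio": 18.0,
    "n_negative_values": 50,
    "n_overflow_values": 50,
    "polyA_spike_ok": False,
    "cRNA_spike_ok": False,
    "rna_deg_slope": 29.0,
}


def simulate_qc_table(
    n_samples: int,
    n_planted_failures: int,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[QCMetrics], list[str]]:
    """QC metric table with ``n_planted_failures`` gross planted failures.

    Passing samples are drawn comfortably inside the default bounds; each
    failure perturbs one randomly chosen fixed-bound metric far beyond its
    bound. Returns the table and the planted failed sample ids.
    """
    if n_planted_failures > n_samples:
        raise ConfigError("n_planted_failures must be <= n_samples")
    if sample_ids is None:
        sample_ids = [f"qc_s{i + 1:02d}" for i in range(n_samples)]
    elif len(sample_ids) != n_samples:
        raise ConfigError("sample_ids length must equal n_samples")
    rng = np.random.default_rng(seed)
    fail_idx = set(
        rng.choice(n_samples, size=n_planted_failures, replace=False).tolist()
    )
    fail_metrics = list(_QC_FAILURE_VALUES)
    table: list[QCMetrics] = []
    failed: list[str] = []
    for i, sid in enumerate(sample_ids):
        fields = {
            "sample_id": sid,
            "avg_intensity": float(rng.uniform(120, 180)),
            "n_negative_values": 0,
            "n_overflow_values": 0,
            "polyA_spike_ok": True,
            "cRNA_spike_ok": True,
            "gapdh_3p5p_ratio": float(rng.uniform(0.8, 2.0)),
            "actb_3p5p_ratio": float(rng.uniform(0.8, 2.2)),
            "center_of_intensity": float(rng.uniform(0.42, 0.58)),
            "pos_border_mean": float(rng.uniform(150, 250)),
            "neg_border_mean": float(rng.uniform(35, 85)),
            "rna_deg_slope": float(rng.uniform(0.5, 2.5)),
        }
        if i in fail_idx:
            metric = fail_metrics[int(rng.integers(len(fail_metrics)))]
            fields[metric] = _QC_FAILURE_VALUES[metric]
            failed.append(sid)
        table.append(QCMetrics(**fields))
    return table, failed
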