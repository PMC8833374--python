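"""File formats: expression TSV, GMT gene sets, model JSON, report tables.

Conventions: tab-separated, UTF-8, "." decimal, "#"-prefixed comment header
lines (tool version, seed, config hash) which every reader ignores.
Expression round-trips are lossless up to 6-significant-digit float
formatting; model files round-trip bit-exactly (full float repr via JSON).

GMT dialect: one pathway per line — name, description, then tab-separated
gene tokens; a plain token is an up-regulated target, a ``GENE|dn`` token a
down-regulated one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import ComparisonResult, ProfileMatch, ReferenceThreshold
from .errors import ConfigError, ParseError
from .expression import ExpressionMatrix
from .gene_sets import TargetGene, TargetGeneSet
from .model import FrozenPathwayModel, GeneParams
from .qc import QCMetrics, QCReport, QCRule, QCRuleSet

COMMENT = "#"


def header_lines(seed: int | None = None, config_hash: str | None = None,
                 extra: Mapping[str, object] | None = None) -> list[str]:
    lines = [f"{COMMENT} stpscore version={__version__}"]
    if seed is not None:
        lines.append(f"{COMMENT} seed={seed}")
    if config_hash is not None:
        lines.append(f"{COMMENT} config_hash={config_hash}")
    for k, v in (extra or {}).items():
        lines.append(f"{COMMENT} {k}={v}")
    return lines


def config_hash(obj) -> str:
    """Short deterministic hash of a config mapping."""
    payload = yaml.safe_dump(obj, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _read_lines(path) -> list[tuple[int, str]]:
    """(1-based line number, content) for non-comment, non-blank lines."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(COMMENT):
                continue
            out.append((i, line))
    return out


# ---------------------------------------------------------------- expression

def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples log2 expression TSV (first column gene_id)."""
    lines = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty expression file")
    hdr_no, hdr = lines[0]
    cols = hdr.split("\t")
    if len(cols) < 2:
        raise ParseError("expression header needs gene_id + >=1 sample", line=hdr_no)
    sample_ids = cols[1:]
    dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dupes:
        raise ParseError(f"duplicate sample id(s) {dupes}", line=hdr_no)
    genes: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for no, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise ParseError(
                f"expected {len(cols)} fields, got {len(parts)}", line=no
            )
        g = parts[0]
        if g in seen:
            raise ParseError(f"duplicate gene id {g!r}", line=no)
        seen.add(g)
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as e:
            raise ParseError(f"non-numeric cell for gene {g!r}: {e}", line=no)
        genes.append(g)
    values = pd.DataFrame(rows, index=genes, columns=sample_ids, dtype=float)
    return ExpressionMatrix(values=values)


def write_expression_tsv(matrix: ExpressionMatrix, path, seed: int | None = None,
                         config_hash: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed, config_hash):
            fh.write(line + "\n")
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for g in matrix.gene_ids:
            row = matrix.values.loc[g]
            fh.write(g + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_annotations_tsv(path) -> pd.DataFrame:
    lines = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty annotation file")
    buf = _io.StringIO("\n".join(l for _, l in lines))
    df = pd.read_csv(buf, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids in annotations")
    return df


def write_annotations_tsv(ann: pd.DataFrame, path, seed: int | None = None,
                          config_hash: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed, config_hash):
            fh.write(line + "\n")
        fh.write("sample_id\t" + "\t".join(map(str, ann.columns)) + "\n")
        for sid, row in ann.iterrows():
            fh.write(str(sid) + "\t" + "\t".join(str(v) for v in row) + "\n")


# ----------------------------------------------------------------------- GMT

def read_gmt(path) -> list[TargetGeneSet]:
    sets = []
    for no, line in _read_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(
                "GMT line needs name, description and >= 1 gene", line=no
            )
        name, desc, tokens = parts[0], parts[1], parts[2:]
        genes = []
        for tok in tokens:
            if not tok:
                raise ParseError(f"empty gene token in set {name!r}", line=no)
            if tok.endswith("|dn"):
                genes.append(TargetGene(tok[: -len("|dn")], "down"))
            else:
                genes.append(TargetGene(tok, "up"))
        try:
            sets.append(TargetGeneSet(name, tuple(genes), source=desc))
        except ConfigError as e:
            raise ParseError(str(e), line=no)
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return sets


def write_gmt(gene_sets: Sequence[TargetGeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            tokens = [
                g.gene_id if g.direction == "up" else f"{g.gene_id}|dn"
                for g in gs.genes
            ]
            fh.write("\t".join([gs.pathway_name, gs.source or "."] + tokens) + "\n")


# -------------------------------------------------------------------- models

def write_models_json(models: Sequence[FrozenPathwayModel], path,
                      seed: int | None = None) -> None:
    """Versioned model file; floats keep full precision so read/write
    round-trips scores bit-exactly."""
    payload = {
        "format": "stpscore-models",
        "version": __version__,
        "seed": seed,
        "models": [
            {
                "pathway_name": m.pathway_name,
                "prior_active": m.prior_active,
                "frozen": m.frozen,
                "calibration_meta": dict(m.calibration_meta),
                "gene_params": {
                    g: {
                        "direction": gp.direction,
                        "cutoff": gp.cutoff,
                        "p_high_given_active": gp.p_high_given_active,
                        "p_high_given_inactive": gp.p_high_given_inactive,
                    }
                    for g, gp in m.gene_params.items()
                },
            }
            for m in models
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_models_json(path) -> list[FrozenPathwayModel]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "stpscore-models":
        raise ParseError(f"{path}: not a stpscore model file")
    models = []
    for m in payload["models"]:
        gene_params = {
            g: GeneParams(
                direction=gp["direction"],
                cutoff=float(gp["cutoff"]),
                p_high_given_active=float(gp["p_high_given_active"]),
                p_high_given_inactive=float(gp["p_high_given_inactive"]),
            )
            for g, gp in m["gene_params"].items()
        }
        models.append(
            FrozenPathwayModel(
                pathway_name=m["pathway_name"],
                prior_active=float(m["prior_active"]),
                gene_params=gene_params,
                frozen=bool(m["frozen"]),
                calibration_meta=m.get("calibration_meta", {}),
            )
        )
    return models


# ------------------------------------------------------------- report tables

def write_scores_tsv(scores: pd.DataFrame, path, seed: int | None = None,
                     config_hash: str | None = None) -> None:
    """Samples x pathways log2-odds table (full float precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed, config_hash):
            fh.write(line + "\n")
        fh.write("sample_id\t" + "\t".join(scores.columns) + "\n")
        for sid, row in scores.iterrows():
            fh.write(str(sid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_scores_tsv(path) -> pd.DataFrame:
    lines = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty scores file")
    buf = _io.StringIO("\n".join(l for _, l in lines))
    df = pd.read_csv(buf, sep="\t", index_col=0)
    return df.astype(float)


def write_thresholds_tsv(thresholds: Sequence[ReferenceThreshold], path,
                         seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed):
            fh.write(line + "\n")
        fh.write("pathway\tref_mean\tref_sd\tupper\tn_ref\tk_sd\n")
        for t in thresholds:
            fh.write(
                f"{t.pathway_name}\t{t.ref_mean!r}\t{t.ref_sd!r}\t{t.upper!r}"
                f"\t{t.n_ref}\t{t.k_sd!r}\n"
            )


def read_thresholds_tsv(path) -> dict[str, ReferenceThreshold]:
    lines = _read_lines(path)
    out: dict[str, ReferenceThreshold] = {}
    for no, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParseError(f"expected 6 fields, got {len(parts)}", line=no)
        out[parts[0]] = ReferenceThreshold(
            pathway_name=parts[0],
            ref_mean=float(parts[1]),
            ref_sd=float(parts[2]),
            upper=float(parts[3]),
            n_ref=int(parts[4]),
            k_sd=float(parts[5]),
        )
    if not out:
        raise ParseError(f"{path}: no thresholds found")
    return out


def write_comparisons_tsv(rows: Sequence[tuple[str, ComparisonResult]], path,
                          seed: int | None = None) -> None:
    """Rows are (comparison label, result); p rendered at 3 decimals for
    display with the full-precision value alongside."""
    from .analysis import bonferroni

    adj = bonferroni([r.p_value for _, r in rows]) if rows else []
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed):
            fh.write(line + "\n")
        fh.write(
            "comparison\tmethod\tstatistic\tp_display\tp_value\t"
            "p_bonferroni\talternative\tn1\tn2\tties_present\n"
        )
        for (label, r), pb in zip(rows, adj):
            fh.write(
                f"{label}\t{r.method}\t{r.statistic!r}\t{r.p_value:.3f}\t"
                f"{r.p_value!r}\t{pb!r}\t{r.alternative}\t{r.n1}\t{r.n2}\t"
                f"{r.ties_present}\n"
            )


def write_classifications_tsv(calls: Mapping[str, Mapping[str, str]], path,
                              seed: int | None = None) -> None:
    """sample -> pathway -> {abnormal_high, normal} matrix."""
    samples = list(calls)
    pathways = list(calls[samples[0]]) if samples else []
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed):
            fh.write(line + "\n")
        fh.write("sample_id\t" + "\t".join(pathways) + "\n")
        for sid in samples:
            fh.write(sid + "\t" + "\t".join(calls[sid][p] for p in pathways) + "\n")


def write_matches_tsv(matches: Sequence[ProfileMatch], path,
                      seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed):
            fh.write(line + "\n")
        fh.write("sample_id\tbest_reference\tsimilarity\tranking\n")
        for m in matches:
            rank = ";".join(f"{l}:{s:.4f}" for l, s in m.ranking)
            fh.write(f"{m.sample_id}\t{m.reference_label}\t{m.similarity!r}\t{rank}\n")


# ----------------------------------------------------------------- QC tables

_QC_COLUMNS = [
    "sample_id", "avg_intensity", "n_negative_values", "n_overflow_values",
    "polyA_spike_ok", "cRNA_spike_ok", "gapdh_3p5p_ratio", "actb_3p5p_ratio",
    "center_of_intensity", "pos_border_mean", "neg_border_mean", "rna_deg_slope",
]


def write_qc_metrics_tsv(metrics: Sequence[QCMetrics], path,
                         seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed):
            fh.write(line + "\n")
        fh.write("\t".join(_QC_COLUMNS) + "\n")
        for m in metrics:
            vals = []
            for c in _QC_COLUMNS:
                v = getattr(m, c)
                vals.append(repr(v) if isinstance(v, float) else str(v))
            fh.write("\t".join(vals) + "\n")


def read_qc_metrics_tsv(path) -> list[QCMetrics]:
    lines = _read_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty QC metrics file")
    hdr_no, hdr = lines[0]
    cols = hdr.split("\t")
    if cols != _QC_COLUMNS:
        raise ParseError(f"unexpected QC columns {cols}", line=hdr_no)
    out = []
    for no, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(_QC_COLUMNS):
            raise ParseError(f"expected {len(_QC_COLUMNS)} fields", line=no)
        rec = dict(zip(_QC_COLUMNS, parts))
        try:
            out.append(
                QCMetrics(
                    sample_id=rec["sample_id"],
                    avg_intensity=float(rec["avg_intensity"]),
                    n_negative_values=int(rec["n_negative_values"]),
                    n_overflow_values=int(rec["n_overflow_values"]),
                    polyA_spike_ok=rec["polyA_spike_ok"] == "True",
                    cRNA_spike_ok=rec["cRNA_spike_ok"] == "True",
                    gapdh_3p5p_ratio=float(rec["gapdh_3p5p_ratio"]),
                    actb_3p5p_ratio=float(rec["actb_3p5p_ratio"]),
                    center_of_intensity=float(rec["center_of_intensity"]),
                    pos_border_mean=float(rec["pos_border_mean"]),
                    neg_border_mean=float(rec["neg_border_mean"]),
                    rna_deg_slope=float(rec["rna_deg_slope"]),
                )
            )
        except ValueError as e:
            raise ParseError(f"bad QC value: {e}", line=no)
    return out


def write_qc_reports_tsv(reports: Sequence[QCReport], path,
                         seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed):
            fh.write(line + "\n")
        fh.write("sample_id\toverall_pass\tfailure_reasons\n")
        for r in reports:
            fh.write(
                f"{r.sample_id}\t{r.overall_pass}\t{'; '.join(r.failure_reasons)}\n"
            )


def write_truth_tsv(truth, path, seed: int | None = None) -> None:
    """Planted activation truth: sample, scenario, then one column per pathway."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines(seed):
            fh.write(line + "\n")
        pathways = list(truth.activation.columns)
        fh.write("sample_id\tscenario\t" + "\t".join(pathways) + "\n")
        for sid, row in truth.activation.iterrows():
            fh.write(
                f"{sid}\t{truth.labels[sid]}\t"
                + "\t".join(repr(float(v)) for v in row)
                + "\n"
            )


# -------------------------------------------------------------------- config

def read_qc_rules_yaml(path) -> QCRuleSet:
    """Rule set from YAML: a ``rules:`` list of {metric, min, max,
    require_true, enabled} entries."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "rules" not in payload:
        raise ConfigError(f"{path}: expected a 'rules' list")
    rules = []
    for entry in payload["rules"]:
        rules.append(
            QCRule(
                metric=entry["metric"],
                min=entry.get("min"),
                max=entry.get("max"),
                require_true=bool(entry.get("require_true", False)),
                enabled=bool(entry.get("enabled", True)),
            )
        )
    return QCRuleSet(tuple(rules))


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg
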