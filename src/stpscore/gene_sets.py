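"""Transcription-factor target-gene sets.

A pathway's activity is read out from the transcription of a curated set of
target genes of its associated transcription factor (typically 20-30 genes).
Each target gene carries an expected regulation direction: ``up`` if the gene
is transcribed more strongly when the pathway is active, ``down`` if it is
repressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

DIRECTIONS = ("up", "down")


@dataclass(frozen=True)
class TargetGene:
    gene_id: str
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ConfigError(
                f"direction for {self.gene_id!r} must be one of {DIRECTIONS}, "
                f"got {self.direction!r}"
            )


@dataclass(frozen=True)
class TargetGeneSet:
    """An ordered, direction-annotated target-gene list for one pathway."""

    pathway_name: str
    genes: tuple[TargetGene, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ConfigError(f"gene set {self.pathway_name!r} is empty")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigError(
                f"gene set {self.pathway_name!r} has duplicate gene ids: {dupes}"
            )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)

    def directions(self) -> dict[str, str]:
        return {g.gene_id: g.direction for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)


def make_gene_set(
    pathway_name: str,
    up: list[str] | tuple[str, ...] = (),
    down: list[str] | tuple[str, ...] = (),
    source: str = "",
) -> TargetGeneSet:
    """Convenience constructor from plain up/down gene-id lists."""
    genes = tuple(
        [TargetGene(g, "up") for g in up] + [TargetGene(g, "down") for g in down]
    )
    return TargetGeneSet(pathway_name=pathway_name, genes=genes, source=source)
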