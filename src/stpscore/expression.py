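"""Expression matrices: log2-scale intensities, genes x samples.

The container wraps a pandas DataFrame (rows = gene ids, columns = sample
ids) plus a per-sample annotation table (rows = sample ids). All values are
log2-scale intensities as produced by probe summarisation of expression
microarrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = sorted(v.index[v.index.duplicated()].unique().tolist())
            raise ConfigError(f"duplicate gene ids: {dupes}")
        if v.columns.has_duplicates:
            dupes = sorted(v.columns[v.columns.duplicated()].unique().tolist())
            raise ConfigError(f"duplicate sample ids: {dupes}")
        arr = v.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ConfigError("expression values must be finite")
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=v.columns.copy())
        else:
            missing = [s for s in v.columns if s not in self.annotations.index]
            if missing:
                raise ConfigError(f"annotations missing for samples: {missing}")
            self.annotations = self.annotations.loc[v.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_values(self, sample_id: str) -> dict[str, float]:
        """Gene -> log2 value map for a single sample column."""
        if sample_id not in self.values.columns:
            raise KeyError(sample_id)
        col = self.values[sample_id]
        return {g: float(x) for g, x in col.items()}

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return ExpressionMatrix(
            values=self.values[sample_ids].copy(),
            annotations=self.annotations.loc[sample_ids].copy(),
        )

    def samples_where(self, column: str, value) -> list[str]:
        """Sample ids whose annotation ``column`` equals ``value`` (in order)."""
        ann = self.annotations
        if column not in ann.columns:
            raise KeyError(column)
        return list(ann.index[ann[column] == value])
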