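"""Community matrix container: samples × species read counts plus metadata."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("site", "habitat", "depth", "season")


@dataclass
class CommunityMatrix:
    """Samples × species integer read counts with per-sample metadata.

    ``counts`` rows are samples, columns species (or OTU) names.
    ``metadata`` is indexed by sample and carries at least
    site / habitat / depth / season.  ``marker_id`` records which amplicon
    the counts came from (``None`` for a multi-marker union).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    marker_id: str | None = None

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.index) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        self.metadata = self.metadata.loc[self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, sample_ids) -> "CommunityMatrix":
        return CommunityMatrix(
            self.counts.loc[sample_ids], self.metadata.loc[sample_ids], self.marker_id
        )

    def drop_empty_species(self) -> "CommunityMatrix":
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return CommunityMatrix(self.counts[keep], self.metadata, self.marker_id)

    def union(self, other: "CommunityMatrix") -> "CommunityMatrix":
        """Element-wise sum over the union of species, same samples.

        Used to combine the per-marker matrices into the whole-survey view.
        """
        if set(self.samples) != set(other.samples):
            raise ValueError("union requires identical sample sets")
        counts = self.counts.add(
            other.counts.reindex(index=self.counts.index), fill_value=0
        ).astype(np.int64)
        return CommunityMatrix(counts, self.metadata, None)

    def to_tsv(self, counts_path, metadata_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="sample")
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path, marker_id=None) -> "CommunityMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample")
        meta = pd.read_csv(metadata_path, sep="\t", index_col="sample")
        return cls(counts, meta, marker_id)
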