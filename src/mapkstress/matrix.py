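"""Count and expression matrix containers with TSV round-tripping."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRANSFORM_TAGS = ("counts", "fpkm", "log2_quantile", "logclr", "tmm_cpm")


@dataclass
class CountMatrix:
    """Integer gene × sample count matrix with per-gene transcript lengths."""

    counts: pd.DataFrame      # genes × samples, nonnegative integers
    lengths_bp: pd.Series     # per-gene transcript length in bp

    def __post_init__(self) -> None:
        self.lengths_bp = self.lengths_bp.reindex(self.counts.index)
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.lengths_bp.isna().any():
            missing = self.lengths_bp.index[self.lengths_bp.isna()][:5].tolist()
            raise ValueError(f"genes missing lengths, e.g. {missing}")
        if (self.lengths_bp <= 0).any():
            raise ValueError("gene lengths must be positive")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[genes], self.lengths_bp.loc[genes])

    def to_tsv(self, counts_path, lengths_path=None) -> None:
        self.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
        if lengths_path is not None:
            self.lengths_bp.rename("length_bp").rename_axis("gene_id").to_csv(
                lengths_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, lengths_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)["length_bp"]
        return cls(counts, lengths)


@dataclass
class ExpressionMatrix:
    """Real-valued gene × sample matrix carrying its transform tag."""

    values: pd.DataFrame
    transform: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORM_TAGS:
            raise ValueError(f"unknown transform tag {self.transform!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# transform: {self.transform}\n")
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            self.values.rename_axis("gene_id").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            values = pd.read_csv(fh, sep="\t", index_col=0)
        transform = meta.pop("transform", "counts")
        return cls(values, transform, meta)


def warn_empty(what: str) -> None:
    warnings.warn(f"{what} produced an empty result", stacklevel=3)
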