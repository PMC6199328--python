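"""Samples x features expression container and TSV I/O.

A thin wrapper over a pandas DataFrame (rows = samples, columns = features)
carrying the feature -> gene mapping that isoform- and exon-level analyses
need.  Values are normalized counts (or RPKM for exon matrices); they must be
non-negative and feature ids unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression_tsv", "read_exon_tsv"]


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # samples x features
    feature_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.feature_to_gene:
            # gene-level matrix: every feature is its own gene
            self.feature_to_gene = {f: f for f in self.values.columns}
        missing = set(self.values.columns) - set(self.feature_to_gene)
        if missing:
            raise ValueError(f"features without gene mapping: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.values.columns:
            seen.setdefault(self.feature_to_gene[f], None)
        return list(seen)

    def features_of_gene(self, gene_id: str) -> list[str]:
        return [f for f in self.values.columns if self.feature_to_gene[f] == gene_id]

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return np.log2(self.values + pseudocount)

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[samples], dict(self.feature_to_gene))

    def to_tsv(self, path: str) -> None:
        """Write features x samples TSV with a ``feature_id``/``gene_id`` prefix."""
        out = self.values.T
        out.insert(0, "gene_id", [self.feature_to_gene[f] for f in out.index])
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t", float_format="%.4f")


def read_expression_tsv(path: str) -> ExpressionMatrix:
    """Read a features x samples TSV written by :meth:`ExpressionMatrix.to_tsv`.

    The first column is the feature id; an optional ``gene_id`` column maps
    features to genes (absent for gene-level matrices).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "gene_id" in df.columns:
        mapping = df["gene_id"].to_dict()
        df = df.drop(columns=["gene_id"])
    else:
        mapping = {}
    return ExpressionMatrix(df.T, mapping)


def read_exon_tsv(path: str) -> ExpressionMatrix:
    """Read an exon RPKM TSV with columns gene_id, exon_index, then samples.

    Exon features are encoded as ``"<gene_id>:<exon_index>"`` with
    ``exon_index`` counting in transcription order (1 = 5'-most exon).
    """
    df = pd.read_csv(path, sep="\t")
    feats = df["gene_id"] + ":" + df["exon_index"].astype(str)
    mapping = dict(zip(feats, df["gene_id"]))
    mat = df.drop(columns=["gene_id", "exon_index"]).set_index(feats)
    return ExpressionMatrix(mat.T, mapping)


def exon_feature(gene_id: str, exon_index: int) -> str:
    return f"{gene_id}:{exon_index}"


def split_exon_feature(feature: str) -> tuple[str, int]:
    gene_id, idx = feature.rsplit(":", 1)
    return gene_id, int(idx)
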