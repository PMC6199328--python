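"""Detection of alternatively-transcribed (AT) genes.

AT genes are genes whose expression variance across a cohort is dominated by
transcript-isoform switching rather than overall gene-level change.  They are
found in two steps:

1. a *switch score* per gene -- the mean, over its isoforms, of the
   per-sample variance of ``log2(isoform + 1) - log2(gene + 1)``, i.e. the
   isoform-level variance residual to gene-level variation;
2. genes above a score quantile are kept only if their isoforms split into
   two anti-correlated clusters: average-linkage on ``1 - Pearson r`` of the
   gene-residual log profiles (so shared gene-level variation cannot mask
   the switch), cut into two groups with negative between-cluster mean
   correlation; the cluster with the smaller mean transcript length is the
   *short* cluster.

The switch score is invariant to per-sample library-size scaling because a
constant log shift cancels in the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .annotation import GeneModel
from .matrix import ExpressionMatrix

__all__ = ["ATGeneCall", "switch_score", "call_at_genes", "write_at_calls", "read_at_calls"]


@dataclass
class ATGeneCall:
    gene_id: str
    switch_score: float
    is_AT: bool
    short_cluster: set[str] = field(default_factory=set)
    long_cluster: set[str] = field(default_factory=set)


def switch_score(
    iso_expr: ExpressionMatrix, gene_expr: ExpressionMatrix, gene: str
) -> float:
    """Isoform-level variance residual to gene-level variation (NaN if <2 isoforms)."""
    features = iso_expr.features_of_gene(gene)
    if len(features) < 2:
        return float("nan")
    iso_log = np.log2(iso_expr.values[features].to_numpy() + 1.0)
    gene_log = np.log2(gene_expr.values[gene].to_numpy() + 1.0)
    resid = iso_log - gene_log[:, None]
    return float(resid.var(axis=0, ddof=1).mean())


def _two_clusters(corr: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Average-linkage on 1 - Pearson r, cut into two groups."""
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="average")
    assignment = fcluster(z, t=2, criterion="maxclust")
    ids = list(corr.index)
    a = [f for f, c in zip(ids, assignment) if c == 1]
    b = [f for f, c in zip(ids, assignment) if c == 2]
    return a, b


def _between_cluster_corr(corr: pd.DataFrame, a: list[str], b: list[str]) -> float:
    return float(corr.loc[a, b].to_numpy().mean())


def call_at_genes(
    iso_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    models: dict[str, GeneModel] | None = None,
    quantile: float = 0.90,
) -> list[ATGeneCall]:
    """Call AT genes and partition their isoforms into short/long clusters.

    ``models`` supplies transcript lengths for the short/long assignment;
    without it, isoform ids are ranked by their mean expression rank in the
    bottom half of samples (a fallback for matrices without annotation) --
    supplying models is strongly recommended.
    """
    if list(iso_expr.sample_ids) != list(gene_expr.sample_ids):
        raise ValueError("isoform and gene matrices must share samples")

    scores: dict[str, float] = {}
    for gene in iso_expr.genes():
        if gene in gene_expr.values.columns:
            scores[gene] = switch_score(iso_expr, gene_expr, gene)
    finite = np.array([v for v in scores.values() if np.isfinite(v)])
    if finite.size == 0:
        return [
            ATGeneCall(g, s, False) for g, s in scores.items()
        ]
    threshold = float(np.quantile(finite, quantile))

    iso_lengths: dict[str, float] = {}
    if models:
        for g in models.values():
            for iso in g.isoforms:
                iso_lengths[iso.isoform_id] = iso.transcript_length

    calls: list[ATGeneCall] = []
    log_expr = iso_expr.log2()
    log_gene = np.log2(gene_expr.values + 1.0)
    for gene, score in scores.items():
        call = ATGeneCall(gene, score, False)
        calls.append(call)
        if not np.isfinite(score) or score < threshold:
            continue
        features = iso_expr.features_of_gene(gene)
        # residual to the gene profile: isolates isoform-usage variation
        sub = log_expr[features].sub(log_gene[gene], axis=0)
        if (sub.std(axis=0) < 1e-12).any():
            continue  # constant isoform: no bimodal pattern detectable
        corr = sub.corr(method="pearson")
        a, b = _two_clusters(corr)
        if not a or not b:
            continue
        if _between_cluster_corr(corr, a, b) >= 0.0:
            continue  # mutually positively correlated: no isoform switch
        len_a = np.mean([iso_lengths.get(f, _length_proxy(iso_expr, f)) for f in a])
        len_b = np.mean([iso_lengths.get(f, _length_proxy(iso_expr, f)) for f in b])
        short, long_ = (a, b) if len_a < len_b else (b, a)
        call.is_AT = True
        call.short_cluster = set(short)
        call.long_cluster = set(long_)
    return calls


def _length_proxy(iso_expr: ExpressionMatrix, feature: str) -> float:
    # without annotation, lower-expressed isoforms are taken as the short ones
    return float(iso_expr.values[feature].mean())


def write_at_calls(calls: list[ATGeneCall], path: str) -> None:
    rows = [
        {
            "gene_id": c.gene_id,
            "switch_score": round(c.switch_score, 6) if np.isfinite(c.switch_score) else "NA",
            "is_AT": int(c.is_AT),
            "short_cluster": ",".join(sorted(c.short_cluster)),
            "long_cluster": ",".join(sorted(c.long_cluster)),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_at_calls(path: str) -> list[ATGeneCall]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    calls = []
    for _, row in df.iterrows():
        short = set(str(row["short_cluster"]).split(",")) if pd.notna(row["short_cluster"]) and row["short_cluster"] else set()
        long_ = set(str(row["long_cluster"]).split(",")) if pd.notna(row["long_cluster"]) and row["long_cluster"] else set()
        short.discard("nan")
        long_.discard("nan")
        calls.append(
            ATGeneCall(
                gene_id=row["gene_id"],
                switch_score=float(row["switch_score"]) if pd.notna(row["switch_score"]) else float("nan"),
                is_AT=bool(row["is_AT"]),
                short_cluster=short,
                long_cluster=long_,
            )
        )
    return calls
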