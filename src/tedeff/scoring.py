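"""Per-sample TEdeff score, classification and transcriptomic signature.

The TEdeff (transcript-shortening) score of a sample is the log2 ratio of
the average expression of short-cluster isoforms of AT genes to the average
expression of long-cluster isoforms; samples with score > -1 are classified
TEdeff.  The group signature is the per-gene Welch t-statistic of TEdeff vs
TEprof gene-level expression (log2 scale), against which external expression
profiles can be matched by Spearman correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .at_genes import ATGeneCall
from .matrix import ExpressionMatrix

__all__ = [
    "TEdeffCall",
    "tedeff_score",
    "classify",
    "score_cohort",
    "signature",
    "signature_correlation",
]

DEFAULT_CUTOFF = -1.0
TEDEFF = "TEdeff"
TEPROF = "TEprof"


@dataclass
class TEdeffCall:
    sample_id: str
    score: float
    label: str


def _cluster_features(at_calls: list[ATGeneCall]) -> tuple[list[str], list[str]]:
    short = [f for c in at_calls if c.is_AT for f in sorted(c.short_cluster)]
    long_ = [f for c in at_calls if c.is_AT for f in sorted(c.long_cluster)]
    if not short or not long_:
        raise ValueError("no AT genes callable")
    return short, long_


def tedeff_score(
    iso_expr: ExpressionMatrix,
    at_calls: list[ATGeneCall],
    sample: str,
    pseudocount: float = 1.0,
    per_gene: bool = False,
) -> float:
    """log2 of (mean short-isoform expression + 1) / (mean long + 1).

    By default means pool all isoform cells of all AT genes; ``per_gene``
    instead averages within genes first and then across genes.
    """
    short, long_ = _cluster_features(at_calls)
    row = iso_expr.values.loc[sample]
    if per_gene:
        s_means, l_means = [], []
        for c in at_calls:
            if not c.is_AT:
                continue
            s_means.append(row[sorted(c.short_cluster)].mean())
            l_means.append(row[sorted(c.long_cluster)].mean())
        s, l = float(np.mean(s_means)), float(np.mean(l_means))
    else:
        s, l = float(row[short].mean()), float(row[long_].mean())
    return float(np.log2((s + pseudocount) / (l + pseudocount)))


def classify(score: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """TEdeff iff score > cutoff (strict; the boundary goes to TEprof)."""
    if not np.isfinite(score):
        return "NA"
    return TEDEFF if score > cutoff else TEPROF


def score_cohort(
    iso_expr: ExpressionMatrix,
    at_calls: list[ATGeneCall],
    cutoff: float = DEFAULT_CUTOFF,
    per_gene: bool = False,
) -> list[TEdeffCall]:
    calls = []
    for sample in iso_expr.sample_ids:
        s = tedeff_score(iso_expr, at_calls, sample, per_gene=per_gene)
        calls.append(TEdeffCall(sample, s, classify(s, cutoff)))
    return calls


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sample t of a vs b (positive when mean(a) > mean(b))."""
    t, _ = stats.ttest_ind(a, b, equal_var=False)
    return float(t)


def signature(
    gene_expr: ExpressionMatrix, calls: list[TEdeffCall]
) -> pd.Series:
    """Per-gene Welch t of TEdeff vs TEprof log2 expression difference."""
    deff = [c.sample_id for c in calls if c.label == TEDEFF]
    prof = [c.sample_id for c in calls if c.label == TEPROF]
    if len(deff) < 2 or len(prof) < 2:
        raise ValueError("each group needs >=2 samples for the signature")
    log = gene_expr.log2()
    a = log.loc[deff].to_numpy()
    b = log.loc[prof].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)  # zero-variance genes carry no signal
    return pd.Series(t, index=gene_expr.values.columns, name="t")


def signature_correlation(
    sample_profile: pd.Series, sig: pd.Series, min_genes: int = 10
) -> tuple[float, float]:
    """Spearman rho (+ two-sided p) of a z-normalized profile vs the signature."""
    shared = sample_profile.index.intersection(sig.index)
    if len(shared) < min_genes:
        raise ValueError(f"only {len(shared)} shared genes (need >= {min_genes})")
    x = sample_profile.loc[shared].to_numpy(dtype=float)
    y = sig.loc[shared].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("constant profile: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def write_calls(calls: list[TEdeffCall], path: str) -> None:
    pd.DataFrame(
        [
            {"sample_id": c.sample_id, "score": round(c.score, 6), "label": c.label}
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def read_calls(path: str) -> list[TEdeffCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        TEdeffCall(row["sample_id"], float(row["score"]), row["label"])
        for _, row in df.iterrows()
    ]
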