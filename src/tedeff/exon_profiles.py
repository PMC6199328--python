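"""5'->3' differential exon profiles and Class I/II gene calling.

For every expressed gene, the per-exon Welch t-statistic of TEdeff vs TEprof
exon expression (RPKM) is computed and the exon vector is mapped onto 20
bins ordered 5'->3' (genes with more than 20 exons are compressed by
averaging, genes with fewer are stretched by nearest-position replication;
a 20-exon gene maps identically).  Gene classes are then called from the bin
vector: Class I genes lose gene-body expression but gain at the 3'-terminal
bin; Class II genes are broadly overexpressed.  The same group-difference
t-statistic, computed on methylation beta-values over a transcript-relative
grid, yields the methylation meta-profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .matrix import ExpressionMatrix, split_exon_feature
from .scoring import TEDEFF, TEPROF, TEdeffCall

__all__ = [
    "ExonBinProfile",
    "expressed_filter",
    "exon_t_stats",
    "bin20",
    "build_profiles",
    "call_gene_classes",
    "class_feature_contrast",
    "methylation_metaprofile",
]

N_BINS = 20
BODY_BINS = (2, 17)  # 1-based inclusive bin range scored as gene body
TERMINAL_BIN = 20
EXPRESSED_PERCENTILE = 90.0
EXPRESSED_CUTOFF = 30.0


@dataclass
class ExonBinProfile:
    gene_id: str
    bins: np.ndarray  # 20 t-statistics, 5' first
    gene_class: str = "neutral"  # I | II | neutral

    @property
    def body_mean_t(self) -> float:
        lo, hi = BODY_BINS
        return float(self.bins[lo - 1 : hi].mean())

    @property
    def terminal_t(self) -> float:
        return float(self.bins[TERMINAL_BIN - 1])

    @property
    def overall_mean_t(self) -> float:
        return float(self.bins.mean())


def expressed_filter(gene_expr: ExpressionMatrix) -> set[str]:
    """Genes whose 90th-percentile normalized count across samples exceeds 30."""
    if gene_expr.values.empty:
        return set()
    pct = np.percentile(gene_expr.values.to_numpy(), EXPRESSED_PERCENTILE, axis=0)
    return {
        g
        for g, p in zip(gene_expr.values.columns, pct)
        if p > EXPRESSED_CUTOFF
    }


def _group_samples(calls: list[TEdeffCall]) -> tuple[list[str], list[str]]:
    deff = [c.sample_id for c in calls if c.label == TEDEFF]
    prof = [c.sample_id for c in calls if c.label == TEPROF]
    if len(deff) < 2 or len(prof) < 2:
        raise ValueError("both groups need >=2 samples")
    return deff, prof


def exon_t_stats(
    exon_expr: ExpressionMatrix,
    calls: list[TEdeffCall],
    statistic: str = "t",
) -> dict[str, np.ndarray]:
    """Per-gene 5'->3' vectors of per-exon Welch t (TEdeff minus TEprof).

    ``statistic="signed_log10p"`` emits sign(t) * -log10(p) instead, the
    variant used for small cell-line panels where the t itself is unstable.
    Exons with zero variance in both groups get a statistic of 0.
    """
    deff, prof = _group_samples(calls)
    a = exon_expr.values.loc[deff].to_numpy()
    b = exon_expr.values.loc[prof].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    if statistic == "t":
        vals = np.where(np.isfinite(t), t, 0.0)
    elif statistic == "signed_log10p":
        with np.errstate(divide="ignore"):
            vals = np.sign(t) * -np.log10(np.clip(p, 1e-300, None))
        vals = np.where(np.isfinite(vals), vals, 0.0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    per_gene: dict[str, list[tuple[int, float]]] = {}
    for feat, v in zip(exon_expr.feature_ids, vals):
        gid, idx = split_exon_feature(feat)
        per_gene.setdefault(gid, []).append((idx, float(v)))
    return {
        gid: np.array([v for _, v in sorted(pairs)])
        for gid, pairs in per_gene.items()
    }


def bin20(values: np.ndarray) -> np.ndarray:
    """Map a per-exon vector (5'->3') onto 20 bins.

    Exon i of n sits at fractional position (i - 0.5)/n.  With n >= 20 each
    bin averages the exons falling in its interval ((j-1)/20, j/20];
    with n < 20 each bin takes the exon nearest its own center, so every
    bin is filled and n = 20 is the identity.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("empty exon vector")
    if n >= N_BINS:
        pos = (np.arange(1, n + 1) - 0.5) / n
        # position p belongs to bin j iff (j-1)/20 < p <= j/20
        bin_idx = np.ceil(pos * N_BINS).astype(int) - 1
        bin_idx = np.clip(bin_idx, 0, N_BINS - 1)
        out = np.zeros(N_BINS)
        for j in range(N_BINS):
            members = values[bin_idx == j]
            out[j] = members.mean() if members.size else np.nan
        # n >= 20 guarantees every bin has at least one member
        return out
    pos = (np.arange(1, n + 1) - 0.5) / n
    centers = (np.arange(1, N_BINS + 1) - 0.5) / N_BINS
    nearest = np.abs(centers[:, None] - pos[None, :]).argmin(axis=1)
    return values[nearest]


def build_profiles(
    exon_expr: ExpressionMatrix,
    calls: list[TEdeffCall],
    expressed: set[str] | None = None,
    statistic: str = "t",
) -> list[ExonBinProfile]:
    """Exon t-statistics binned to 20-vectors for every (expressed) gene."""
    t_map = exon_t_stats(exon_expr, calls, statistic=statistic)
    profiles = []
    for gid in sorted(t_map):
        if expressed is not None and gid not in expressed:
            continue
        profiles.append(ExonBinProfile(gid, bin20(t_map[gid])))
    return profiles


def call_gene_classes(
    profiles: list[ExonBinProfile], t0: float = 2.0
) -> list[ExonBinProfile]:
    """Label profiles: Class I = body loss plus terminal gain, Class II =
    overall overexpression, else neutral.  Mutates and returns ``profiles``."""
    for p in profiles:
        if p.body_mean_t <= -t0 and p.terminal_t >= t0:
            p.gene_class = "I"
        elif p.overall_mean_t >= t0:
            p.gene_class = "II"
        else:
            p.gene_class = "neutral"
    return profiles


def class_feature_contrast(
    profiles: list[ExonBinProfile], models: dict[str, GeneModel]
) -> pd.DataFrame:
    """Genomic length and exon-density contrast of Class I vs Class II genes.

    Returns one row per feature (log10 genomic length; mRNA/genomic-length
    ratio) with per-class means and the two-sample Welch t and p.
    """
    class1 = [models[p.gene_id] for p in profiles if p.gene_class == "I" and p.gene_id in models]
    class2 = [models[p.gene_id] for p in profiles if p.gene_class == "II" and p.gene_id in models]
    rows = []
    for name, fn in (
        ("log10_genomic_length", lambda g: np.log10(g.genomic_length)),
        ("mrna_genomic_ratio", lambda g: g.exon_density),
    ):
        a = np.array([fn(g) for g in class1])
        b = np.array([fn(g) for g in class2])
        if a.size == 0 or b.size == 0:
            rows.append({"feature": name, "class1_mean": np.nan, "class2_mean": np.nan, "t": np.nan, "p": np.nan, "n1": a.size, "n2": b.size})
            continue
        if a.size < 2 or b.size < 2 or (a.std() == 0 and b.std() == 0):
            t, p = (0.0, 1.0) if (a.size and b.size and a.mean() == b.mean()) else (np.nan, np.nan)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "feature": name,
                "class1_mean": float(a.mean()),
                "class2_mean": float(b.mean()),
                "t": float(t),
                "p": float(p),
                "n1": int(a.size),
                "n2": int(b.size),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# methylation meta-profile


def _transcript_relative(
    g: GeneModel, pos: int, flank: int
) -> float | None:
    """Map a genomic position to the meta-gene axis.

    Axis units: [-1, 0) upstream flank (fraction of ``flank``), [0, 1] scaled
    gene body, (1, 2] downstream flank.  Returns None outside the window.
    """
    if g.strand == "+":
        rel = pos - g.tss
    else:
        rel = g.tss - pos
    glen = g.genomic_length
    if -flank <= rel < 0:
        return rel / flank  # in [-1, 0)
    if 0 <= rel <= glen:
        return rel / glen if glen > 0 else 0.0
    if glen < rel <= glen + flank:
        return 1.0 + (rel - glen) / flank
    return None


def methylation_metaprofile(
    beta: pd.DataFrame,
    calls: list[TEdeffCall],
    models: dict[str, GeneModel],
    flank: int = 2000,
    n_flank_bins: int = 5,
    n_body_bins: int = 20,
    min_probes: int = 3,
) -> pd.DataFrame:
    """Per-position-bin Welch t of beta-values, TEdeff minus TEprof.

    ``beta`` carries columns probe_id, chrom, pos, gene_id and one column per
    sample.  Probes are mapped to a transcript-relative axis (upstream flank,
    body scaled to unit length, downstream flank) and, per bin, the per-sample
    mean beta over the bin's probes is compared between groups.  Bins with
    fewer than ``min_probes`` probes are NA.
    """
    deff, prof = _group_samples(calls)
    sample_cols = deff + prof

    edges = np.concatenate(
        [
            np.linspace(-1.0, 0.0, n_flank_bins, endpoint=False),
            np.linspace(0.0, 1.0, n_body_bins, endpoint=False),
            np.linspace(1.0, 2.0, n_flank_bins, endpoint=False),
            [2.0],
        ]
    )
    n_bins = len(edges) - 1
    assigned: list[list[int]] = [[] for _ in range(n_bins)]
    for row_i, row in enumerate(beta.itertuples(index=False)):
        g = models.get(row.gene_id)
        if g is None:
            continue
        x = _transcript_relative(g, int(row.pos), flank)
        if x is None:
            continue
        j = int(np.searchsorted(edges, x, side="right")) - 1
        j = min(max(j, 0), n_bins - 1)
        assigned[j].append(row_i)

    vals = beta[sample_cols].to_numpy()
    records = []
    for j in range(n_bins):
        center = (edges[j] + edges[j + 1]) / 2.0
        idx = assigned[j]
        if len(idx) < min_probes:
            records.append({"position": center, "t": np.nan, "n_probes": len(idx)})
            continue
        per_sample = vals[idx].mean(axis=0)
        a = per_sample[: len(deff)]
        b = per_sample[len(deff) :]
        t, _ = stats.ttest_ind(a, b, equal_var=False)
        records.append(
            {"position": center, "t": float(t) if np.isfinite(t) else 0.0, "n_probes": len(idx)}
        )
    return pd.DataFrame(records)
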