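"""ChIP coverage tracks, meta-gene profiles and RNAP II traveling ratios.

Coverage is held run-length encoded per chromosome (bedGraph in, per-base
out).  A meta-gene profile length-normalizes every gene body onto a common
101-point grid (cubic-spline sampling of the per-base coverage, linear for
very short genes), flanked by fixed-length windows, and scales depth per
million reads.  The traveling ratio of a gene is the mean occupancy over the
gene body divided by the mean occupancy in a window around the TSS; low
values indicate promoter-proximal stalling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .annotation import GeneModel
from .matrix import ExpressionMatrix

__all__ = [
    "CoverageTrack",
    "TravelingRatio",
    "metagene_profile",
    "traveling_ratio",
    "traveling_ratios",
    "occupancy_expression_correlation",
]

DEFAULT_FLANK = 2000
BODY_POINTS = 101
FLANK_POINTS = 100
TSS_HALF_WINDOW = 300


class CoverageTrack:
    """Run-length per-base coverage over chromosomes.

    ``library_size`` (total reads) scales profiles to per-million-reads; when
    not supplied it is estimated as total coverage area divided by the read
    length (default 50 bp).
    """

    def __init__(
        self,
        runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: float | None = None,
        read_length: int = 50,
    ):
        self._runs = runs
        if library_size is None:
            area = sum(
                float(((e - s) * v).sum()) for s, e, v in runs.values()
            )
            library_size = max(area / read_length, 1.0)
        self.library_size = float(library_size)

    @classmethod
    def from_bedgraph(
        cls, path: str, library_size: float | None = None, read_length: int = 50
    ) -> "CoverageTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split("\t")[:4]
                by_chrom.setdefault(chrom, []).append((int(s), int(e), float(v)))
        runs = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.array(rows, dtype=float)
            runs[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return cls(runs, library_size=library_size, read_length=read_length)

    @classmethod
    def from_array(
        cls, chrom: str, depth: np.ndarray, library_size: float | None = None
    ) -> "CoverageTrack":
        depth = np.asarray(depth, dtype=float)
        starts = np.arange(len(depth), dtype=np.int64)
        return cls(
            {chrom: (starts, starts + 1, depth)}, library_size=library_size
        )

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end); bases without coverage are 0."""
        out = np.zeros(end - start, dtype=float)
        entry = self._runs.get(chrom)
        if entry is None or end <= start:
            return out
        starts, ends, vals = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(int(starts[i]), start)
            e = min(int(ends[i]), end)
            if e > s:
                out[s - start : e - start] = vals[i]
        return out

    def scale(self, c: float) -> "CoverageTrack":
        runs = {
            chrom: (s.copy(), e.copy(), v * c)
            for chrom, (s, e, v) in self._runs.items()
        }
        return CoverageTrack(runs, library_size=self.library_size * c)


@dataclass
class TravelingRatio:
    gene_id: str
    tss_occupancy: float
    body_occupancy: float

    @property
    def tr(self) -> float:
        if self.tss_occupancy <= 0:
            return float("nan")
        return self.body_occupancy / self.tss_occupancy


def _oriented(vec: np.ndarray, strand: str) -> np.ndarray:
    return vec if strand == "+" else vec[::-1]


def _sample_body(vec: np.ndarray, n_points: int) -> np.ndarray:
    """Length-normalize a per-base vector to ``n_points`` via spline sampling."""
    L = len(vec)
    grid = np.linspace(0, L - 1, n_points)
    if L < 4:
        return np.interp(grid, np.arange(L), vec)
    spline = CubicSpline(np.arange(L), vec)
    return spline(grid)


def metagene_profile(
    track: CoverageTrack,
    models: dict[str, GeneModel],
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Mean per-position coverage profile across genes, per million reads.

    Grid: ``FLANK_POINTS`` upstream points (fixed 20 bp step over the flank),
    101 body points on a unit-length axis, ``FLANK_POINTS`` downstream
    points; strand-aware so position 0 is always the TSS.  Genes shorter
    than 2 grid steps are skipped.
    """
    step = flank // FLANK_POINTS
    per_gene = []
    scale = 1e6 / track.library_size
    for gid in sorted(models):
        g = models[gid]
        if g.genomic_length < 4:
            continue
        lo = max(0, g.start - flank)
        pad_left = flank - (g.start - lo)
        raw = track.depth(g.chrom, lo, g.end + flank)
        vec = np.concatenate([np.zeros(pad_left), raw])
        up = vec[:flank]
        body = vec[flank : flank + g.genomic_length]
        down = vec[flank + g.genomic_length :]
        if g.strand == "-":
            up, body, down = down[::-1], body[::-1], up[::-1]
        prof = np.concatenate(
            [
                up[::step][:FLANK_POINTS],
                _sample_body(body, BODY_POINTS),
                down[::step][:FLANK_POINTS],
            ]
        )
        per_gene.append(prof * scale)
    if not per_gene:
        raise ValueError("no genes usable for the meta-profile")
    mat = np.vstack(per_gene)
    x = np.concatenate(
        [
            np.linspace(-1.0, 0.0, FLANK_POINTS, endpoint=False),
            np.linspace(0.0, 1.0, BODY_POINTS),
            np.linspace(1.0, 2.0, FLANK_POINTS + 1)[1:],
        ]
    )
    assert mat.shape[1] == FLANK_POINTS + BODY_POINTS + FLANK_POINTS
    return pd.DataFrame(
        {"position": x, "coverage": mat.mean(axis=0), "n_genes": len(per_gene)}
    )


def traveling_ratio(
    track: CoverageTrack,
    model: GeneModel,
    tss_half_window: int = TSS_HALF_WINDOW,
) -> TravelingRatio:
    """Body/TSS occupancy ratio of one gene.

    TSS occupancy is the mean depth over TSS +/- ``tss_half_window``; body
    occupancy the mean depth from ``tss_half_window`` past the TSS (in
    transcription direction) to the gene end.
    """
    g = model
    if g.genomic_length <= tss_half_window:
        raise ValueError(f"{g.gene_id}: gene shorter than the TSS window")
    w_start = max(0, g.tss - tss_half_window)
    w_end = g.tss + tss_half_window
    tss_occ = float(track.depth(g.chrom, w_start, w_end).mean())
    if g.strand == "+":
        body = track.depth(g.chrom, w_end, g.end)
    else:
        body = track.depth(g.chrom, g.start, w_start)
    body_occ = float(body.mean()) if len(body) else 0.0
    return TravelingRatio(g.gene_id, tss_occ, body_occ)


def traveling_ratios(
    track: CoverageTrack, models: dict[str, GeneModel], **kwargs
) -> pd.DataFrame:
    rows = []
    for gid in sorted(models):
        try:
            r = traveling_ratio(track, models[gid], **kwargs)
        except ValueError:
            continue
        rows.append(
            {
                "gene_id": r.gene_id,
                "tss_occupancy": r.tss_occupancy,
                "body_occupancy": r.body_occupancy,
                "tr": r.tr,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def occupancy_expression_correlation(
    body_occupancy: pd.Series,
    gene_expr: ExpressionMatrix,
    sample: str,
    min_genes: int = 20,
) -> float:
    """Spearman rho of gene-body occupancy vs the sample's expression."""
    expr = gene_expr.values.loc[sample]
    shared = body_occupancy.index.intersection(expr.index)
    if len(shared) < min_genes:
        raise ValueError(f"only {len(shared)} shared genes (need >= {min_genes})")
    x = body_occupancy.loc[shared].to_numpy(dtype=float)
    y = expr.loc[shared].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
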