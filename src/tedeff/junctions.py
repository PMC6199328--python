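"""Splice-junction read counting and intron-retention scoring.

For every annotated intron (consecutive union exons of a gene) three read
classes are tallied from spliced alignments:

* exon-exon (EE): gapped alignments whose N gap coincides exactly with the
  intron and that align at least ``anchor`` bases on each flanking exon;
* exon-intron (EI) / intron-exon (IE): alignments that run *ungapped* across
  the donor (left) or acceptor (right) boundary with at least ``anchor``
  bases on each side, starting within ``window`` bp of the boundary --
  evidence of unspliced, intron-retaining transcripts.

Only reads with mapping quality strictly greater than ``mapq_min`` count.
The per-sample retention ratio sums (EI + IE) / EE over eligible junctions
(EE >= 5 reads and intron length > 500 bp).  Junction coordinates follow the
genomic orientation: donor = left exon end, acceptor = right exon start,
regardless of strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModel

__all__ = [
    "JunctionCounts",
    "RetentionScore",
    "count_junctions",
    "retention_score",
    "score_samples",
    "median_split",
]

DEFAULT_MAPQ_MIN = 20  # strict: MAPQ must exceed this
DEFAULT_ANCHOR = 8  # inclusive: 8 aligned bases suffice
DEFAULT_WINDOW = 150  # read must start within +/-150 bp of the boundary
MIN_EE_READS = 5
MIN_INTRON_LENGTH = 500

_REF_OPS = {0, 2, 7, 8}  # M, D, =, X consume reference without a gap
_SKIP_OP = 3  # N
_SUPPORTED_OPS = {0, 1, 2, 3, 4, 7, 8}  # M I D N S = X


@dataclass
class JunctionCounts:
    gene_id: str
    donor: int  # end of the genomically-left exon (0-based, exclusive)
    acceptor: int  # start of the genomically-right exon
    ee_reads: int = 0
    ei_reads: int = 0
    ie_reads: int = 0

    @property
    def intron_length(self) -> int:
        return self.acceptor - self.donor

    @property
    def eligible(self) -> bool:
        return self.ee_reads >= MIN_EE_READS and self.intron_length > MIN_INTRON_LENGTH


@dataclass
class RetentionScore:
    sample_id: str
    ratio: float
    n_eligible: int


def _reference_blocks(cigartuples) -> list[tuple[int, int]] | None:
    """Maximal ungapped reference blocks (lengths relative to pos 0).

    Returns None when the CIGAR contains unsupported operations.  M/D/=/X
    extend the current block; N closes it; I/S consume no reference.
    """
    blocks: list[tuple[int, int]] = []
    cur_start, cur = 0, 0
    open_block = False
    for op, length in cigartuples:
        if op not in _SUPPORTED_OPS:
            return None
        if op in _REF_OPS:
            if not open_block:
                cur_start = cur
                open_block = True
            cur += length
        elif op == _SKIP_OP:
            if open_block:
                blocks.append((cur_start, cur))
                open_block = False
            cur += length
        # I and S: no reference advance
    if open_block:
        blocks.append((cur_start, cur))
    return blocks


def _junction_index(models: dict[str, GeneModel]):
    """Per-chromosome lookup tables over all annotated junctions."""
    by_chrom: dict[str, dict] = {}
    all_counts: list[JunctionCounts] = []
    for gid in sorted(models):
        g = models[gid]
        tab = by_chrom.setdefault(
            g.chrom, {"gap": {}, "bpos": [], "bref": []}
        )
        exons = g.exons_genomic()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            jc = JunctionCounts(gid, e1, s2)
            all_counts.append(jc)
            tab["gap"].setdefault((e1, s2), []).append(jc)
            tab["bpos"].extend([e1, s2])
            tab["bref"].extend([(jc, "donor"), (jc, "acceptor")])
    for tab in by_chrom.values():
        order = np.argsort(np.array(tab["bpos"], dtype=int), kind="stable")
        tab["bpos"] = np.array(tab["bpos"], dtype=int)[order]
        tab["bref"] = [tab["bref"][i] for i in order]
    return by_chrom, all_counts


def count_junctions(
    aln_path: str,
    models: dict[str, GeneModel],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    anchor: int = DEFAULT_ANCHOR,
    window: int = DEFAULT_WINDOW,
) -> list[JunctionCounts]:
    """Stream a SAM/BAM once and tally EE/EI/IE reads per annotated junction.

    Junctions are enumerated from the annotation (union exons per gene);
    de-novo gaps not matching an annotated intron are ignored.  Reads with
    unsupported CIGAR operations are skipped and counted in a warning.
    """
    by_chrom, all_counts = _junction_index(models)
    skipped_cigar = 0
    with pysam.AlignmentFile(aln_path, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.mapping_quality <= mapq_min:
                continue
            tab = by_chrom.get(read.reference_name)
            if tab is None:
                continue
            blocks = _reference_blocks(read.cigartuples or [])
            if blocks is None:
                skipped_cigar += 1
                continue
            start = read.reference_start
            abs_blocks = [(start + s, start + e) for s, e in blocks]

            # exon-exon: each N gap between consecutive blocks
            for (s1, e1), (s2, e2) in zip(abs_blocks, abs_blocks[1:]):
                jcs = tab["gap"].get((e1, s2))
                if jcs and (e1 - s1) >= anchor and (e2 - s2) >= anchor:
                    for jc in jcs:
                        jc.ee_reads += 1

            # exon-intron / intron-exon: boundaries crossed ungapped
            bpos = tab["bpos"]
            for bs, be in abs_blocks:
                lo = int(np.searchsorted(bpos, bs + anchor, side="left"))
                hi = int(np.searchsorted(bpos, be - anchor, side="right"))
                for k in range(lo, hi):
                    b = int(bpos[k])
                    if abs(start - b) > window:
                        continue
                    jc, kind = tab["bref"][k]
                    if kind == "donor":
                        jc.ei_reads += 1
                    else:
                        jc.ie_reads += 1
    if skipped_cigar:
        warnings.warn(
            f"{skipped_cigar} reads with unsupported CIGAR ops skipped",
            stacklevel=2,
        )
    return all_counts


def retention_score(
    counts: list[JunctionCounts],
    gene_set: set[str] | None = None,
    sample_id: str = "",
) -> RetentionScore:
    """(sum EI + IE) / (sum EE) over eligible junctions of ``gene_set``.

    Junctions with fewer than 5 EE reads or intron length <= 500 bp are
    excluded from numerator and denominator alike.
    """
    eligible = [
        c
        for c in counts
        if c.eligible and (gene_set is None or c.gene_id in gene_set)
    ]
    if not eligible:
        warnings.warn("no eligible junctions; retention score is NA", stacklevel=2)
        return RetentionScore(sample_id, float("nan"), 0)
    ee = sum(c.ee_reads for c in eligible)
    retained = sum(c.ei_reads + c.ie_reads for c in eligible)
    return RetentionScore(sample_id, retained / ee, len(eligible))


def score_samples(
    sam_paths: dict[str, str],
    models: dict[str, GeneModel],
    gene_set: set[str] | None = None,
    **kwargs,
) -> pd.Series:
    """Per-sample retention ratios over ``gene_set`` (e.g. Class I genes)."""
    out = {}
    for sid in sorted(sam_paths):
        counts = count_junctions(sam_paths[sid], models, **kwargs)
        out[sid] = retention_score(counts, gene_set, sid).ratio
    return pd.Series(out, name="retention_ratio")


def median_split(scores: pd.Series) -> tuple[list[str], list[str]]:
    """Split samples at the median score: (above-median, at-or-below).

    Ties at the median go to the low group; with an even sample count and
    distinct values the split is exactly half and half.  A constant vector
    cannot be split and raises.
    """
    if len(scores) < 2:
        raise ValueError("need >=2 samples for a median split")
    vals = scores.to_numpy(dtype=float)
    if np.allclose(vals, vals[0]):
        raise ValueError("degenerate split: all scores identical")
    med = float(np.median(vals))
    high = [s for s, v in scores.items() if v > med]
    low = [s for s, v in scores.items() if v <= med]
    return high, low


def write_counts(counts: list[JunctionCounts], path: str) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "donor": c.donor,
                "acceptor": c.acceptor,
                "ee": c.ee_reads,
                "ei": c.ei_reads,
                "ie": c.ie_reads,
                "intron_length": c.intron_length,
            }
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)
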