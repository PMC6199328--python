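"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's parsing and counting code paths:
the junction scanner re-parses raw SAM text and marks aligned reference
positions base by base; the overlap counter paints dataset intervals onto a
per-base array.
"""

from __future__ import annotations

import re

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def brute_force_junction_counts(
    sam_text: str,
    junctions: list[tuple[int, int]],
    mapq_min: int = 20,
    anchor: int = 8,
    window: int = 150,
) -> dict[tuple[int, int], dict[str, int]]:
    """Count EE/EI/IE reads per junction by per-base scanning of SAM text."""
    counts = {j: {"ee": 0, "ei": 0, "ie": 0} for j in junctions}
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        flag = int(fields[1])
        if flag & 4:  # unmapped
            continue
        pos0 = int(fields[3]) - 1
        mapq = int(fields[4])
        if mapq <= mapq_min:
            continue
        ops = _CIGAR_RE.findall(fields[5])
        if fields[5] == "*" or any(op in "HP" for _, op in ops):
            continue
        aligned: set[int] = set()
        gaps: list[tuple[int, int]] = []
        ref = pos0
        for length, op in ops:
            n = int(length)
            if op in "MDX=":
                aligned.update(range(ref, ref + n))
                ref += n
            elif op == "N":
                gaps.append((ref, ref + n))
                ref += n
            # I and S consume no reference

        for donor, acceptor in junctions:
            tally = counts[(donor, acceptor)]
            # exon-exon: a gap exactly matching the intron, anchored both sides
            if (donor, acceptor) in gaps:
                left = 0
                p = donor - 1
                while p in aligned:
                    left += 1
                    p -= 1
                right = 0
                p = acceptor
                while p in aligned:
                    right += 1
                    p += 1
                if left >= anchor and right >= anchor:
                    tally["ee"] += 1
            # boundary crossings, ungapped: all bases through the window present
            for boundary, key in ((donor, "ei"), (acceptor, "ie")):
                if abs(pos0 - boundary) > window:
                    continue
                span = range(boundary - anchor, boundary + anchor)
                if all(p in aligned for p in span):
                    tally[key] += 1
    return counts


def brute_force_overlap(regions, dataset, universe: int = 100_000) -> int:
    """Query regions overlapping the dataset, counted by per-base marking."""
    marked: dict[str, bytearray] = {}
    for iv in dataset:
        arr = marked.setdefault(iv.chrom, bytearray(universe))
        for p in range(max(0, iv.start), min(universe, iv.end)):
            arr[p] = 1
    n = 0
    for iv in regions:
        arr = marked.get(iv.chrom)
        if arr is None:
            continue
        if any(arr[p] for p in range(max(0, iv.start), min(universe, iv.end))):
            n += 1
    return n
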