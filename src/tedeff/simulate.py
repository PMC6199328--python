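"""Synthetic tumor-cohort generator with planted elongation defects.

The generator emits a fully self-contained bundle -- annotation (GTF),
isoform/gene/exon expression matrices (TSV), per-sample spliced alignments
(SAM), per-sample RNAP II coverage (bedGraph), a methylation beta matrix, a
clinical table and a ground-truth JSON -- in which a configurable fraction of
samples carries a defective-transcription-elongation (TEdeff) phenotype:

* AT genes switch usage from the long full-length isoform toward a 5'
  truncated short isoform (log2 short/long ratio shifted by ``isoform_shift``);
* long Class I genes lose gene-body exon expression and gain 3'-terminal
  exon expression; short Class II genes are broadly overexpressed;
* exon-intron junction-spanning (unspliced) reads appear at an elevated
  per-junction rate;
* RNAP II coverage is TSS-peaked with a reduced gene-body traveling ratio;
* DNA methylation dips at the TSS and rises in the gene body;
* survival times carry a configurable hazard ratio.

Counts are negative-binomial around group-specific means (gene-level
over-dispersion plus a shared per-sample library factor), so isoform- and
exon-level analyses face realistic RNA-seq noise.  A fixed seed yields a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, IsoformModel, write_annotation
from .matrix import ExpressionMatrix, exon_feature

__all__ = ["CohortConfig", "CohortBundle", "generate_cohort", "worked_example_fixtures"]

READ_LENGTH = 50  # bp, single-end


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Defaults describe a 60-sample cohort with 25% TEdeff prevalence and a
    2-unit log2 shift of short/long isoform usage; gene classes are planted
    with the length contrast the phenotype predicts (Class I long, Class II
    short).
    """

    n_samples: int = 60
    frac_tedeff: float = 0.25
    n_genes: int = 80
    frac_at: float = 0.10
    frac_class1: float = 0.20
    frac_class2: float = 0.20
    class1_length_range: tuple[int, int] = (50_000, 200_000)
    class2_length_range: tuple[int, int] = (2_000, 15_000)
    isoform_shift: float = 2.0
    baseline_log_ratio: float = -2.5  # log2 short/long usage in TEprof samples
    usage_noise_at: float = 1.0  # sample-level sd of the log2 usage ratio, AT genes
    usage_noise: float = 0.10  # same for non-AT genes (stable usage)
    body_loss: float = 0.4
    terminal_gain: float = 4.0
    class2_gain: float = 2.0
    retention_rate_tedeff: float = 0.12
    retention_rate_teprof: float = 0.02
    tr_tedeff: float = 0.2
    tr_teprof: float = 0.8
    hazard_ratio: float = 3.0
    dispersion: float = 0.2
    junction_depth: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_tedeff": self.frac_tedeff,
            "frac_at": self.frac_at,
            "frac_class1": self.frac_class1,
            "frac_class2": self.frac_class2,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        for name in ("retention_rate_tedeff", "retention_rate_teprof"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if round(self.n_samples * self.frac_tedeff) < 1:
            raise ValueError("cohort must contain at least one TEdeff sample")
        if self.frac_at + self.frac_class1 + self.frac_class2 > 1.0:
            raise ValueError("gene-role fractions exceed 1")

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("class1_length_range", "class2_length_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CohortBundle:
    """All generated artifacts, on disk and in memory."""

    out_dir: str
    genes: dict[str, GeneModel]
    iso_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    exon_expr: ExpressionMatrix
    methylation: pd.DataFrame
    clinical: pd.DataFrame
    truth: dict
    gtf_path: str
    sam_paths: dict[str, str]
    coverage_paths: dict[str, str]

    @property
    def sample_labels(self) -> dict[str, str]:
        return self.truth["samples"]

    @property
    def gene_classes(self) -> dict[str, str]:
        return self.truth["gene_classes"]


# ---------------------------------------------------------------------------
# gene construction


@dataclass
class _GeneSpec:
    model: GeneModel
    role: str  # class1 | class2 | at | neutral
    mu: float  # baseline mean normalized count
    short_k: int  # number of 5' exons in the short isoform


_MARKER_GENES = ("GZMK", "PRF1")  # cytolytic TIL markers, planted neutral

_THERAPY_POOL = [
    ("Interferon alfa-2b", 0.15),
    ("Proleukin", 0.10),
    ("IL-2", 0.10),
    ("ipilimumab", 0.10),
    ("Pembrolizumab", 0.10),
    ("Sunitinib", 0.20),
    ("Sorafenib", 0.10),
    ("Gemcitabine", 0.15),
]


def _draw_gene_structure(
    rng: np.random.Generator, role: str, cfg: CohortConfig, cursor: int, gene_id: str
) -> tuple[_GeneSpec, int]:
    if role == "class1":
        n_exons = int(rng.integers(15, 26))
        glen = int(rng.integers(*cfg.class1_length_range))
    elif role == "class2":
        n_exons = int(rng.integers(4, 9))
        glen = int(rng.integers(*cfg.class2_length_range))
    elif role == "at":
        n_exons = int(rng.integers(8, 15))
        glen = int(rng.integers(20_000, 80_000))
    else:
        n_exons = int(rng.integers(4, 11))
        glen = int(rng.integers(5_000, 40_000))

    exon_lens = rng.integers(120, 301, size=n_exons)
    min_len = int(exon_lens.sum() + 150 * (n_exons - 1))
    glen = max(glen, min_len)
    total_intron = glen - int(exon_lens.sum())
    if n_exons > 1:
        w = rng.uniform(0.5, 1.5, size=n_exons - 1)
        intron_lens = np.maximum(100, (total_intron * w / w.sum()).astype(int))
    else:
        intron_lens = np.array([], dtype=int)

    exons_genomic: list[tuple[int, int]] = []
    pos = cursor
    for i, elen in enumerate(exon_lens):
        exons_genomic.append((pos, pos + int(elen)))
        pos += int(elen)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    strand = "+" if rng.random() < 0.5 else "-"
    exons_tx = exons_genomic if strand == "+" else exons_genomic[::-1]

    short_k = max(2, n_exons // 3) if n_exons >= 3 else 1
    long_iso = IsoformModel(f"{gene_id}.L", gene_id, list(exons_tx), "full-length")
    short_iso = IsoformModel(
        f"{gene_id}.S", gene_id, list(exons_tx[:short_k]), "truncated"
    )
    model = GeneModel(
        gene_id=gene_id,
        chrom="chr1",
        strand=strand,  # type: ignore[arg-type]
        tss=0,
        tts=0,
        exons=list(exons_tx),
        isoforms=[long_iso, short_iso],
    )
    if strand == "+":
        model.tss, model.tts = model.start, model.end - 1
    else:
        model.tss, model.tts = model.end - 1, model.start

    mu = float(10 ** rng.uniform(1.7, 2.7))
    spec = _GeneSpec(model=model, role=role, mu=mu, short_k=short_k)
    return spec, pos + 10_000  # intergenic gap


def _assign_roles(rng: np.random.Generator, cfg: CohortConfig) -> list[str]:
    n1 = round(cfg.n_genes * cfg.frac_class1)
    n2 = round(cfg.n_genes * cfg.frac_class2)
    nat = round(cfg.n_genes * cfg.frac_at)
    roles = (
        ["class1"] * n1
        + ["class2"] * n2
        + ["at"] * nat
        + ["neutral"] * (cfg.n_genes - n1 - n2 - nat)
    )
    return [roles[i] for i in rng.permutation(len(roles))]


# ---------------------------------------------------------------------------
# expression


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = m + d m^2 (gamma-Poisson mixture)."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(float)


def _short_fraction(log_ratio: float) -> float:
    r = 2.0**log_ratio
    return r / (1.0 + r)


def _simulate_expression(
    rng: np.random.Generator,
    cfg: CohortConfig,
    specs: list[_GeneSpec],
    is_tedeff: np.ndarray,
    sample_ids: list[str],
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix]:
    n = cfg.n_samples
    lib = np.exp(rng.normal(0.0, 0.2, size=n))  # shared library-size factor

    iso_cols: dict[str, np.ndarray] = {}
    iso_map: dict[str, str] = {}
    exon_cols: dict[str, np.ndarray] = {}
    exon_map: dict[str, str] = {}
    gene_cols: dict[str, np.ndarray] = {}

    base_short = _short_fraction(cfg.baseline_log_ratio)
    for spec in specs:
        g = spec.model
        bio = np.exp(rng.normal(0.0, 0.4, size=n))  # per-sample gene factor
        mu_s = spec.mu * lib * bio

        if spec.role == "at":
            log_ratio = (
                cfg.baseline_log_ratio
                + cfg.isoform_shift * is_tedeff
                + rng.normal(0.0, cfg.usage_noise_at, size=n)
            )
        else:
            log_ratio = cfg.baseline_log_ratio + rng.normal(0.0, cfg.usage_noise, size=n)
        sfrac = np.array([_short_fraction(r) for r in log_ratio])

        short = _nb_draw(rng, mu_s * sfrac, cfg.dispersion)
        long = _nb_draw(rng, mu_s * (1.0 - sfrac), cfg.dispersion)
        iso_cols[f"{g.gene_id}.S"] = short
        iso_cols[f"{g.gene_id}.L"] = long
        iso_map[f"{g.gene_id}.S"] = g.gene_id
        iso_map[f"{g.gene_id}.L"] = g.gene_id
        gene_cols[g.gene_id] = short + long

        n_ex = g.n_exons
        u = rng.uniform(0.7, 1.3, size=n_ex)  # static per-exon efficiency
        for j in range(1, n_ex + 1):
            factor = np.ones(n)
            if spec.role == "class1":
                if j == n_ex:
                    factor = np.where(is_tedeff, cfg.terminal_gain, 1.0)
                elif j > 1:
                    factor = np.where(is_tedeff, cfg.body_loss, 1.0)
            elif spec.role == "class2":
                factor = np.where(is_tedeff, cfg.class2_gain, 1.0)
            elif spec.role == "at" and j > spec.short_k:
                # 3' exons are covered by the long isoform only
                factor = (1.0 - sfrac) / (1.0 - base_short)
            mean = mu_s * u[j - 1] * factor
            counts = _nb_draw(rng, mean, cfg.dispersion)
            exon_len_kb = (g.exons[j - 1][1] - g.exons[j - 1][0]) / 1000.0
            feat = exon_feature(g.gene_id, j)
            exon_cols[feat] = counts / exon_len_kb / 10.0  # RPKM-like scale
            exon_map[feat] = g.gene_id

    iso = ExpressionMatrix(
        pd.DataFrame(iso_cols, index=sample_ids), iso_map
    )
    gene = ExpressionMatrix(pd.DataFrame(gene_cols, index=sample_ids))
    exon = ExpressionMatrix(
        pd.DataFrame(exon_cols, index=sample_ids), exon_map
    )
    return iso, gene, exon


# ---------------------------------------------------------------------------
# alignments


def _sam_header(genome_len: int) -> str:
    return f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:{genome_len}\n"


def _write_sample_sam(
    path: str,
    rng: np.random.Generator,
    specs: list[_GeneSpec],
    retention_rate: float,
    depth: float,
    genome_len: int,
) -> None:
    lines: list[str] = [_sam_header(genome_len)]
    counter = 0
    seq = "A" * READ_LENGTH
    for spec in specs:
        exons = spec.model.exons_genomic()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            donor, acceptor = e1, s2
            gap = acceptor - donor
            n_reads = rng.poisson(depth)
            for _ in range(n_reads):
                a = int(rng.integers(10, 41))  # bases left of the boundary
                mapq = int(rng.integers(0, 21)) if rng.random() < 0.03 else 60
                flag = 16 if rng.random() < 0.5 else 0
                if rng.random() < retention_rate:
                    boundary = donor if rng.random() < 0.5 else acceptor
                    pos = boundary - a
                    cigar = f"{READ_LENGTH}M"
                else:
                    pos = donor - a
                    cigar = f"{a}M{gap}N{READ_LENGTH - a}M"
                counter += 1
                lines.append(
                    f"r{counter:07d}\t{flag}\tchr1\t{pos + 1}\t{mapq}\t{cigar}"
                    f"\t*\t0\t0\t{seq}\t*\n"
                )
    with open(path, "w") as fh:
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# coverage


def _write_sample_bedgraph(
    path: str,
    rng: np.random.Generator,
    specs: list[_GeneSpec],
    tr_target: float,
) -> None:
    tss_half = 300
    rows: list[tuple[int, int, float]] = []
    for spec in specs:
        g = spec.model
        d_tss = float(rng.gamma(20.0, 2.5))  # mean 50
        tr = float(np.clip(tr_target * rng.lognormal(0.0, 0.15), 0.01, 5.0))
        w_start = max(0, g.tss - tss_half)
        w_end = g.tss + tss_half
        body = (w_end, g.end) if g.strand == "+" else (g.start, w_start)
        rows.append((w_start, w_end, d_tss))
        if body[1] > body[0]:
            rows.append((body[0], body[1], d_tss * tr))
    rows.sort()
    with open(path, "w") as fh:
        for s, e, v in rows:
            fh.write(f"chr1\t{s}\t{e}\t{v:.3f}\n")


# ---------------------------------------------------------------------------
# methylation


def _probe_layout() -> list[tuple[str, str, float]]:
    """(zone, label, position) where position is bp offset or body fraction."""
    layout: list[tuple[str, str, float]] = []
    for off in (-1800, -1200, -600):
        layout.append(("upstream", f"u{-off}", off))
    for off in (-100, 0, 100):
        layout.append(("tss", f"t{off}", off))
    for frac in (0.15, 0.30, 0.45, 0.60, 0.75, 0.90):
        layout.append(("body", f"b{int(frac * 100)}", frac))
    layout.append(("tts", "e0", 0))
    for off in (600, 1200):
        layout.append(("downstream", f"d{off}", off))
    return layout


_ZONE_BASE = {"upstream": 0.50, "tss": 0.15, "body": 0.65, "tts": 0.50, "downstream": 0.50}
_ZONE_TEDEFF_DELTA = {"upstream": 0.0, "tss": -0.08, "body": 0.10, "tts": -0.05, "downstream": 0.0}


def _probe_position(g: GeneModel, zone: str, pos: float) -> int:
    direction = 1 if g.strand == "+" else -1
    if zone in ("upstream", "tss"):
        return max(0, g.tss + direction * int(pos))
    if zone == "body":
        return int(round(g.tss + direction * pos * g.genomic_length))
    # tts / downstream, offset past the TTS
    return max(0, g.tts + direction * int(pos))


def _simulate_methylation(
    rng: np.random.Generator,
    specs: list[_GeneSpec],
    is_tedeff: np.ndarray,
    sample_ids: list[str],
) -> pd.DataFrame:
    layout = _probe_layout()
    records: list[dict] = []
    for spec in specs:
        g = spec.model
        for zone, label, pos in layout:
            base = _ZONE_BASE[zone] + rng.normal(0.0, 0.03)
            delta = _ZONE_TEDEFF_DELTA[zone]
            beta = base + delta * is_tedeff + rng.normal(0.0, 0.05, size=len(is_tedeff))
            beta = np.clip(beta, 0.01, 0.99)
            rec = {
                "probe_id": f"{g.gene_id}_{label}",
                "chrom": g.chrom,
                "pos": _probe_position(g, zone, pos),
                "gene_id": g.gene_id,
            }
            rec.update({sid: round(float(b), 4) for sid, b in zip(sample_ids, beta)})
            records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# clinical


def _simulate_clinical(
    rng: np.random.Generator,
    cfg: CohortConfig,
    is_tedeff: np.ndarray,
    sample_ids: list[str],
) -> pd.DataFrame:
    base_scale = 600.0
    censor_time = 1500.0
    names = [t[0] for t in _THERAPY_POOL]
    probs = np.array([t[1] for t in _THERAPY_POOL])
    probs = probs / probs.sum()
    rows = []
    for sid, deff in zip(sample_ids, is_tedeff):
        scale = base_scale / (cfg.hazard_ratio if deff else 1.0)
        t = float(rng.exponential(scale))
        event = 1 if t <= censor_time else 0
        rows.append(
            {
                "sample_id": sid,
                "time": round(min(t, censor_time), 1),
                "event": event,
                "therapy": names[rng.choice(len(names), p=probs)],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# driver


def generate_cohort(cfg: CohortConfig, out_dir: str) -> CohortBundle:
    """Generate the full synthetic bundle under ``out_dir``.

    Identical configs (including seed) produce byte-identical files.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    os.makedirs(out_dir, exist_ok=True)
    os.makedirs(os.path.join(out_dir, "sam"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "coverage"), exist_ok=True)

    roles = _assign_roles(rng, cfg)
    specs: list[_GeneSpec] = []
    cursor = 10_000
    markers = list(_MARKER_GENES)
    for i, role in enumerate(roles):
        gene_id = f"G{i + 1:04d}"
        if role == "neutral" and markers:
            gene_id = markers.pop(0)
        spec, cursor = _draw_gene_structure(rng, role, cfg, cursor, gene_id)
        specs.append(spec)
    genome_len = cursor + 10_000

    n_tedeff = round(cfg.n_samples * cfg.frac_tedeff)
    labels = np.array([True] * n_tedeff + [False] * (cfg.n_samples - n_tedeff))
    labels = labels[rng.permutation(cfg.n_samples)]
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]

    iso, gene, exon = _simulate_expression(rng, cfg, specs, labels, sample_ids)
    methylation = _simulate_methylation(rng, specs, labels, sample_ids)
    clinical = _simulate_clinical(rng, cfg, labels, sample_ids)

    gtf_path = os.path.join(out_dir, "annotation.gtf")
    write_annotation([s.model for s in specs], gtf_path)
    iso.to_tsv(os.path.join(out_dir, "isoform_expression.tsv"))
    gene.to_tsv(os.path.join(out_dir, "gene_expression.tsv"))

    exon_rows = []
    for feat in exon.feature_ids:
        gid, idx = feat.rsplit(":", 1)
        exon_rows.append([gid, int(idx)] + list(exon.values[feat].round(4)))
    exon_df = pd.DataFrame(exon_rows, columns=["gene_id", "exon_index"] + sample_ids)
    exon_df.to_csv(os.path.join(out_dir, "exon_expression.tsv"), sep="\t", index=False)

    methylation.to_csv(os.path.join(out_dir, "methylation.tsv"), sep="\t", index=False)
    clinical.to_csv(os.path.join(out_dir, "clinical.tsv"), sep="\t", index=False)

    sam_paths: dict[str, str] = {}
    coverage_paths: dict[str, str] = {}
    for sid, deff in zip(sample_ids, labels):
        rate = cfg.retention_rate_tedeff if deff else cfg.retention_rate_teprof
        tr = cfg.tr_tedeff if deff else cfg.tr_teprof
        sam_path = os.path.join(out_dir, "sam", f"{sid}.sam")
        _write_sample_sam(sam_path, rng, specs, rate, cfg.junction_depth, genome_len)
        cov_path = os.path.join(out_dir, "coverage", f"{sid}.bedgraph")
        _write_sample_bedgraph(cov_path, rng, specs, tr)
        sam_paths[sid] = sam_path
        coverage_paths[sid] = cov_path

    role_to_class = {"class1": "I", "class2": "II", "at": "neutral", "neutral": "neutral"}
    truth = {
        "samples": {
            sid: ("TEdeff" if deff else "TEprof")
            for sid, deff in zip(sample_ids, labels)
        },
        "gene_classes": {s.model.gene_id: role_to_class[s.role] for s in specs},
        "gene_roles": {s.model.gene_id: s.role for s in specs},
        "at_genes": {
            s.model.gene_id: {
                "short": [f"{s.model.gene_id}.S"],
                "long": [f"{s.model.gene_id}.L"],
            }
            for s in specs
            if s.role == "at"
        },
        "config": dataclasses.asdict(cfg),
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    return CohortBundle(
        out_dir=out_dir,
        genes={s.model.gene_id: s.model for s in specs},
        iso_expr=iso,
        gene_expr=gene,
        exon_expr=exon,
        methylation=methylation,
        clinical=clinical,
        truth=truth,
        gtf_path=gtf_path,
        sam_paths=sam_paths,
        coverage_paths=coverage_paths,
    )


# ---------------------------------------------------------------------------
# worked-example fixtures


def worked_example_fixtures() -> dict:
    """Tiny printed-input fixtures for the two in-text worked examples.

    * A region-enrichment scenario: 100 query promoters of which exactly 50
      overlap a peak set, drawn from a 1000-gene background in which 10% of
      promoters carry a peak (so a matched permutation expects ~10 overlaps);
      the canonical expectation quoted with the example is 10 +/- 5.
    * A 42-sample retention-score vector with distinct values, which a median
      split divides into two groups of 21.
    """
    chrom = "chrF"
    background: list[GeneModel] = []
    peaks: list[GenomicInterval] = []
    for i in range(1000):
        s = 2_000 + i * 3_000  # promoter [s, s+1001)
        tss = s + 1_000
        gene = GeneModel(
            gene_id=f"B{i:04d}",
            chrom=chrom,
            strand="+",
            tss=tss,
            tts=tss + 399,
            exons=[(tss, tss + 400)],
        )
        background.append(gene)
        if i % 10 == 0:  # 10% of background promoters carry a peak
            peaks.append(GenomicInterval(chrom, s + 400, s + 600))

    hits = [g for i, g in enumerate(background) if i % 10 == 0]
    misses = [g for i, g in enumerate(background) if i % 10 != 0]
    query = hits[:50] + misses[:50]

    rng = np.random.default_rng(42)
    scores = np.round(np.sort(rng.uniform(0.01, 0.60, size=42)), 6)
    # distinct by construction of a continuous draw; enforce anyway
    assert len(set(scores)) == 42
    retention = pd.Series(scores, index=[f"V{i + 1:02d}" for i in range(42)])

    return {
        "query_genes": query,
        "background_genes": background,
        "peaks": peaks,
        "expected_mean": 10.0,
        "expected_sd": 5.0,
        "retention_scores": retention,
    }
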