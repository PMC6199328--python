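"""Cohort outcome stratification: Kaplan-Meier, Cox Wald tests, TIL score.

Groups (TEdeff vs TEprof, therapy classes, TIL-high vs TIL-low and their
two-factor combinations) are compared by a single-covariate Cox
proportional-hazards model; the reported p-value is the Wald test on the
group coefficient, with the log-rank test emitted alongside.  The TIL
(tumor-infiltrating-lymphocyte) score of a sample is the mean log2
expression of the cytolytic markers GZMK and PRF1, median-split into
high/low (ties go to the low group).
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from .junctions import median_split
from .matrix import ExpressionMatrix
from .scoring import TEDEFF, TEdeffCall

__all__ = [
    "load_therapy_vocabulary",
    "classify_therapy",
    "load_clinical",
    "km_estimate",
    "compare_groups",
    "til_score",
    "two_factor_strata",
]

TIL_MARKERS = ("GZMK", "PRF1")


def load_therapy_vocabulary(path: str | None = None) -> dict[str, str]:
    """Raw drug annotation -> therapy class, lower-cased for exact matching."""
    if path is None:
        source = resources.files("tedeff.data").joinpath("therapy_vocabulary.tsv")
        df = pd.read_csv(source.open(), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return {
        str(raw).strip().lower(): cls
        for raw, cls in zip(df["raw"], df["therapy_class"])
    }


def classify_therapy(raw: str, vocabulary: dict[str, str] | None = None) -> str:
    """Case-insensitive exact match against the drug vocabulary; else 'other'."""
    if vocabulary is None:
        vocabulary = load_therapy_vocabulary()
    return vocabulary.get(str(raw).strip().lower(), "other")


def load_clinical(path: str, vocabulary: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a clinical TSV (sample_id, time, event, therapy) and classify therapy."""
    df = pd.read_csv(path, sep="\t")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be binary 0/1")
    if "therapy" in df.columns:
        if vocabulary is None:
            vocabulary = load_therapy_vocabulary()
        df["therapy_class"] = [classify_therapy(t, vocabulary) for t in df["therapy"]]
    return df


def km_estimate(group: pd.DataFrame, label: str = "KM") -> KaplanMeierFitter:
    """Product-limit survival estimate of one group (right-censoring respected)."""
    if len(group) == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter(label=label)
    kmf.fit(group["time"], group["event"])
    return kmf


def compare_groups(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, float]:
    """Cox Wald test (primary) and log-rank test of group a vs group b.

    The Cox model regresses the hazard on a single indicator (1 = group a);
    the returned hazard ratio is for group a relative to group b.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >=2 subjects")
    n_events = int(a["event"].sum() + b["event"].sum())
    if n_events == 0:
        return {
            "hazard_ratio": float("nan"),
            "wald_z": float("nan"),
            "wald_p": float("nan"),
            "logrank_p": float("nan"),
            "n_a": len(a),
            "n_b": len(b),
        }
    df = pd.concat(
        [a.assign(group=1), b.assign(group=0)], ignore_index=True
    )[["time", "event", "group"]]
    if df["group"].nunique() < 2:
        raise ValueError("group indicator is constant")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary.loc["group"]
    lr = logrank_test(a["time"], b["time"], a["event"], b["event"])
    return {
        "hazard_ratio": float(np.exp(summary["coef"])),
        "wald_z": float(summary["z"]),
        "wald_p": float(summary["p"]),
        "logrank_p": float(lr.p_value),
        "n_a": len(a),
        "n_b": len(b),
    }


def til_score(
    gene_expr: ExpressionMatrix, markers: tuple[str, ...] = TIL_MARKERS
) -> pd.DataFrame:
    """Mean log2 marker expression per sample, median-split into high/low."""
    available = [m for m in markers if m in gene_expr.values.columns]
    if not available:
        raise ValueError(f"none of the marker genes {markers} present")
    if len(available) < len(markers):
        warnings.warn(
            f"markers missing, using {available} only", stacklevel=2
        )
    log = gene_expr.log2()
    score = log[available].mean(axis=1)
    high, low = median_split(score)
    group = pd.Series("TIL-low", index=score.index, name="group")
    group.loc[high] = "TIL-high"
    return pd.DataFrame({"score": score, "group": group})


def two_factor_strata(
    clinical: pd.DataFrame,
    calls: list[TEdeffCall],
    second: pd.Series,
    second_name: str = "TIL",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Four strata from TEdeff status crossed with a binary second factor.

    ``second`` maps sample_id -> one of two level names.  Returns the strata
    (possibly empty, reported with n=0) and the pairwise Cox/log-rank
    comparison table over non-degenerate pairs.
    """
    levels = sorted(second.dropna().unique())
    if len(levels) > 2:
        raise ValueError(f"second factor must be binary, got {levels}")
    label_of = {c.sample_id: c.label for c in calls}
    cl = clinical.set_index("sample_id")

    strata: dict[str, pd.DataFrame] = {}
    for te in (TEDEFF, "TEprof"):
        for lv in levels:
            key = f"{te}/{lv}"
            ids = [
                s
                for s in cl.index
                if label_of.get(s) == te and s in second.index and second[s] == lv
            ]
            strata[key] = cl.loc[ids].reset_index()

    rows = []
    keys = list(strata)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            a, b = strata[ka], strata[kb]
            if len(a) < 2 or len(b) < 2:
                continue
            try:
                res = compare_groups(a, b)
            except ValueError:
                continue
            rows.append({"stratum_a": ka, "stratum_b": kb, **res})
    return strata, pd.DataFrame(rows)
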