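import numpy as np
import pandas as pd
import pytest

from conftest import truth_calls
from tedeff.matrix import ExpressionMatrix
from tedeff.survival import (
    classify_therapy,
    compare_groups,
    km_estimate,
    load_clinical,
    load_therapy_vocabulary,
    til_score,
    two_factor_strata,
)


def tbl(times, events):
    return pd.DataFrame({"time": times, "event": events})


def test_km_no_events_stays_at_one():
    kmf = km_estimate(tbl([5.0, 8.0, 12.0], [0, 0, 0]))
    assert float(kmf.predict(12.0)) == 1.0


def test_km_two_events_product_limit_by_hand():
    kmf = km_estimate(tbl([1.0, 2.0], [1, 1]))
    assert float(kmf.predict(1.5)) == pytest.approx(0.5)
    assert float(kmf.predict(2.0)) == pytest.approx(0.0)


def test_censoring_before_first_event_does_not_change_curve():
    # hand computation: at t=1 risk set {b, c} -> S = 1/2; at t=2 risk {c} -> 0
    with_cens = km_estimate(tbl([0.5, 1.0, 2.0], [0, 1, 1]))
    without = km_estimate(tbl([1.0, 2.0], [1, 1]))
    for t in (1.0, 1.5, 2.0):
        assert float(with_cens.predict(t)) == pytest.approx(float(without.predict(t)))


def test_compare_groups_detects_planted_hazard():
    rng = np.random.default_rng(4)
    a = tbl(rng.exponential(200, 50).round(2), np.ones(50, dtype=int))
    b = tbl(rng.exponential(600, 50).round(2), np.ones(50, dtype=int))
    res = compare_groups(a, b)
    assert res["hazard_ratio"] > 1.5
    assert res["wald_p"] < 0.01
    assert res["logrank_p"] < 0.01


def test_compare_groups_power_at_hazard_ratio_three():
    rng = np.random.default_rng(6)
    hits = 0
    n_sim = 100
    for _ in range(n_sim):
        t_a = rng.exponential(200, 50)
        t_b = rng.exponential(600, 50)
        a = tbl(np.minimum(t_a, 1500).round(2), (t_a <= 1500).astype(int))
        b = tbl(np.minimum(t_b, 1500).round(2), (t_b <= 1500).astype(int))
        hits += compare_groups(a, b)["wald_p"] < 0.05
    assert hits / n_sim >= 0.8


def test_compare_groups_edge_cases():
    with pytest.raises(ValueError):
        compare_groups(tbl([1.0], [1]), tbl([1.0, 2.0], [1, 1]))
    res = compare_groups(tbl([1.0, 2.0], [0, 0]), tbl([3.0, 4.0], [0, 0]))
    assert np.isnan(res["wald_p"])  # no events: NA


def test_therapy_vocabulary_case_insensitive_exact_match():
    vocab = load_therapy_vocabulary()
    assert classify_therapy("Proleukin", vocab) == "immunotherapy"
    assert classify_therapy("PROLEUKIN", vocab) == "immunotherapy"
    assert classify_therapy("ipilimumab", vocab) == "checkpoint"
    assert classify_therapy("Yervoy", vocab) == "checkpoint"
    assert classify_therapy("Sunitinib", vocab) == "targeted"
    assert classify_therapy("mystery drug", vocab) == "other"
    # exact match only: substrings do not classify
    assert classify_therapy("Proleukin plus", vocab) == "other"


def test_load_clinical_classifies_therapy(small_cohort):
    import os

    cl = load_clinical(os.path.join(small_cohort.out_dir, "clinical.tsv"))
    assert set(cl["therapy_class"]) <= {"immunotherapy", "checkpoint", "targeted", "other"}
    assert (cl["time"] > 0).all()


def _marker_expr(gzmk, prf1, samples):
    return ExpressionMatrix(pd.DataFrame({"GZMK": gzmk, "PRF1": prf1}, index=samples))


def test_til_score_median_split_and_fallback():
    samples = [f"s{i}" for i in range(42)]
    rng = np.random.default_rng(2)
    gzmk = rng.uniform(1, 100, 42)
    prf1 = rng.uniform(1, 100, 42)
    til = til_score(_marker_expr(gzmk, prf1, samples))
    assert (til["group"] == "TIL-high").sum() == 21
    assert (til["group"] == "TIL-low").sum() == 21

    # single-marker fallback preserves that marker's ranking
    single = ExpressionMatrix(pd.DataFrame({"GZMK": gzmk}, index=samples))
    with pytest.warns(UserWarning, match="markers missing"):
        til_single = til_score(single)
    assert (til_single["score"].rank() == pd.Series(gzmk, index=samples).rank()).all()

    with pytest.raises(ValueError, match="none of the marker genes"):
        til_score(ExpressionMatrix(pd.DataFrame({"OTHER": gzmk}, index=samples)))


def test_til_score_degenerate_when_markers_constant():
    samples = [f"s{i}" for i in range(6)]
    with pytest.raises(ValueError, match="degenerate"):
        til_score(_marker_expr([5.0] * 6, [5.0] * 6, samples))


def test_two_factor_strata_counts_and_planted_worst_stratum():
    rng = np.random.default_rng(8)
    n = 120
    samples = [f"s{i}" for i in range(n)]
    deff = np.arange(n) < n // 2
    til_low = rng.permutation(np.arange(n) % 2 == 0)
    # worst hazard in TEdeff/TIL-low, best in TEprof/TIL-high
    scale = np.where(deff & til_low, 100, np.where(~deff & ~til_low, 900, 350))
    times = rng.exponential(scale)
    clin = pd.DataFrame(
        {
            "sample_id": samples,
            "time": np.minimum(times, 1200).round(2),
            "event": (times <= 1200).astype(int),
        }
    )
    from tedeff.scoring import TEdeffCall

    calls = [
        TEdeffCall(s, 0.0 if d else -2.0, "TEdeff" if d else "TEprof")
        for s, d in zip(samples, deff)
    ]
    second = pd.Series(
        ["TIL-low" if t else "TIL-high" for t in til_low], index=samples
    )
    strata, comparisons = two_factor_strata(clin, calls, second)
    assert set(strata) == {
        "TEdeff/TIL-high",
        "TEdeff/TIL-low",
        "TEprof/TIL-high",
        "TEprof/TIL-low",
    }
    assert sum(len(s) for s in strata.values()) == n
    t_med = float(np.median(clin["time"]))
    surv = {k: float(km_estimate(s).predict(t_med)) for k, s in strata.items() if len(s)}
    assert min(surv, key=surv.get) == "TEdeff/TIL-low"
    assert max(surv, key=surv.get) == "TEprof/TIL-high"
    assert len(comparisons) == 6


def test_two_factor_strata_constant_second_factor_reduces_to_two():
    samples = [f"s{i}" for i in range(8)]
    clin = pd.DataFrame(
        {"sample_id": samples, "time": np.arange(1.0, 9.0), "event": [1] * 8}
    )
    from tedeff.scoring import TEdeffCall

    calls = [
        TEdeffCall(s, 0.0 if i < 4 else -2.0, "TEdeff" if i < 4 else "TEprof")
        for i, s in enumerate(samples)
    ]
    second = pd.Series(["same"] * 8, index=samples)
    strata, _ = two_factor_strata(clin, calls, second)
    nonempty = [k for k, v in strata.items() if len(v)]
    assert len(nonempty) == 2


def test_cohort_survival_separates_planted_hazard(default_cohort):
    b = default_cohort
    cl = b.clinical
    labels = b.truth["samples"]
    a = cl[[labels[s] == "TEdeff" for s in cl["sample_id"]]]
    bb = cl[[labels[s] == "TEprof" for s in cl["sample_id"]]]
    res = compare_groups(a, bb)
    assert res["hazard_ratio"] > 1.0
    assert res["wald_p"] < 0.05
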