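"""Scoring inferred migration graphs against ground truth.

Migration inference is scored on directed source→recipient site pairs:
true positives are inferred pairs present in the truth, false positives are
inferred pairs absent from the truth, and false negatives are true pairs
not inferred.  Precision, recall, and their harmonic mean (F1) summarize a
method's accuracy; per-class breakdowns (P→M, M→M, M→P) localize where a
model errs.  Benchmark-level aggregation mirrors the standard summaries:
per-model mean F1, LRT rejection percentages, best-AICc percentages, and
mean multiple-range counts, optionally split by tumor-count group (m5/m8)
and seeding scenario (mS/pS/pM/pR).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .ancestral import PATH_CLASSES, MigrationGraph, classify_pair


@dataclass(frozen=True)
class EvaluationResult:
    TP: int
    FP: int
    FN: int

    @property
    def precision(self) -> float:
        if self.TP + self.FP == 0:
            return 1.0 if self.FN == 0 else 0.0
        return self.TP / (self.TP + self.FP)

    @property
    def recall(self) -> float:
        if self.TP + self.FN == 0:
            return 1.0 if self.FP == 0 else 0.0
        return self.TP / (self.TP + self.FN)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if p + r == 0:
            return 0.0
        return 2 * p * r / (p + r)


def _check_same_sites(inferred: MigrationGraph, truth: MigrationGraph) -> None:
    if {a.label for a in inferred.areas} != {a.label for a in truth.areas}:
        raise ValueError("inferred and truth graphs are over different site sets")


def _inferred_pairs_unique(
    inferred: MigrationGraph, truth_pairs: set[tuple[int, int]]
) -> set[tuple[int, int]]:
    """Directed site pairs claimed by the inferred graph.

    A path whose parent annotation spans several areas yields several
    candidate pairs; credit is given if any candidate matches the truth
    (only the matching candidates are kept), otherwise all candidates count
    as claimed-but-wrong pairs.
    """
    pairs: set[tuple[int, int]] = set()
    for p in inferred.paths:
        cands = set(p.candidate_pairs())
        hit = cands & truth_pairs
        pairs |= hit if hit else cands
    return pairs


def score_paths(
    inferred: MigrationGraph, truth: MigrationGraph, mode: str = "unique-pairs"
) -> EvaluationResult:
    """Precision/recall/F1 of inferred vs true migration paths.

    mode="unique-pairs" (default) deduplicates repeated site pairs before
    matching; mode="multiset" matches pair multiplicities.
    """
    _check_same_sites(inferred, truth)
    if mode == "unique-pairs":
        t = set(truth.pair_multiset())
        i = _inferred_pairs_unique(inferred, t)
        tp = len(i & t)
        return EvaluationResult(TP=tp, FP=len(i) - tp, FN=len(t) - tp)
    if mode == "multiset":
        t = truth.pair_multiset()
        i_counter: Counter = Counter()
        t_set = set(t)
        for p in inferred.paths:
            cands = sorted(set(p.candidate_pairs()))
            hit = [c for c in cands if c in t_set]
            i_counter[hit[0] if hit else cands[0]] += 1
        tp = sum(min(i_counter[k], t[k]) for k in i_counter)
        fp = sum(i_counter.values()) - tp
        fn = sum(t.values()) - tp
        return EvaluationResult(TP=tp, FP=fp, FN=fn)
    raise ValueError(f"unknown scoring mode {mode!r}")


def classify_counts(
    inferred: MigrationGraph, truth: MigrationGraph
) -> dict[str, dict[str, int]]:
    """Correct / erroneous / not-inferred path counts per class.

    Unique-pair matching; each pair is classed by the primary flag of its
    endpoints.  Class sums reproduce the overall TP/FP/FN.
    """
    _check_same_sites(inferred, truth)
    primary = truth.primary_id
    t = set(truth.pair_multiset())
    i = _inferred_pairs_unique(inferred, t)
    out = {c: {"correct": 0, "erroneous": 0, "not_inferred": 0} for c in PATH_CLASSES}
    for s, r in i & t:
        out[classify_pair(s, r, primary)]["correct"] += 1
    for s, r in i - t:
        out[classify_pair(s, r, primary)]["erroneous"] += 1
    for s, r in t - i:
        out[classify_pair(s, r, primary)]["not_inferred"] += 1
    return out


@dataclass
class BenchmarkSummary:
    """Aggregated benchmark tables (all pandas DataFrames)."""

    mean_f1_by_model: pd.DataFrame
    mean_f1_by_model_mgroup: pd.DataFrame
    mean_f1_by_model_scenario: pd.DataFrame
    lrt_rejection_pct: pd.DataFrame
    best_aicc_pct: pd.DataFrame
    mean_multiple_ranges: pd.DataFrame
    class_counts: Optional[pd.DataFrame] = None


def aggregate_benchmark(rows: pd.DataFrame, alpha: float = 0.05) -> BenchmarkSummary:
    """Summaries over per-(dataset, model) result rows.

    ``rows`` must carry columns: dataset, model, family, founder, m_group,
    scenario, f1, AICc, multiple_ranges, and (for base-model rows)
    lrt_p_value of the test against the +J counterpart.  Percentages use
    the per-dataset best-AICc model and LRT rejections at ``alpha``.
    """
    rows = rows.copy()
    mean_f1 = rows.groupby("model", as_index=False)["f1"].mean()
    f1_mg = rows.groupby(["model", "m_group"], as_index=False)["f1"].mean()
    f1_sc = rows.groupby(["model", "scenario"], as_index=False)["f1"].mean()

    base = rows[~rows["founder"] & rows["lrt_p_value"].notna()]
    lrt = (
        base.assign(reject=base["lrt_p_value"] < alpha)
        .groupby("family", as_index=False)["reject"]
        .mean()
    )
    lrt["lrt_pct"] = 100.0 * lrt.pop("reject")

    best = rows.loc[rows.groupby("dataset")["AICc"].idxmin(), ["dataset", "model"]]
    n_datasets = rows["dataset"].nunique()
    pct = (
        best["model"].value_counts().reindex(sorted(rows["model"].unique()), fill_value=0)
        / n_datasets
        * 100.0
    )
    best_pct = pct.rename("best_aicc_pct").rename_axis("model").reset_index()

    multi = rows.groupby("model", as_index=False)["multiple_ranges"].mean()

    class_df = None
    class_cols = [
        c for c in rows.columns if any(c.startswith(f"{cl}_") for cl in ("PM", "MM", "MP"))
    ]
    if class_cols:
        class_df = rows.groupby("model", as_index=False)[class_cols].sum()

    return BenchmarkSummary(
        mean_f1_by_model=mean_f1,
        mean_f1_by_model_mgroup=f1_mg,
        mean_f1_by_model_scenario=f1_sc,
        lrt_rejection_pct=lrt,
        best_aicc_pct=best_pct,
        mean_multiple_ranges=multi,
        class_counts=class_df,
    )
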