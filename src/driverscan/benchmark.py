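"""Benchmarking driver call sets against reference lists.

Precision is the fraction of called elements found in the truth set.
Because the complete set of true drivers per cohort is unknowable, recall
uses a lower-bound denominator: for coding benchmarks the union of all
methods' true positives against a gold-standard gene list, for non-coding
benchmarks the set of elements called by at least ``agreement_k`` methods.
Cohort-level TP/FP/FN counts are pooled by summation (micro-average) by
default; macro-averaging over cohorts is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CallSet",
    "ReferenceSet",
    "read_calls",
    "read_reference",
    "filter_recurrence",
    "coding_benchmark",
    "consensus_benchmark",
]


@dataclass
class CallSet:
    """Driver candidates of one method: rows (cohort, element_id, n_samples)."""

    method: str
    calls: pd.DataFrame  # columns: cohort, element_id, n_samples

    def __post_init__(self):
        self.calls = (
            self.calls.drop_duplicates(subset=["cohort", "element_id"])
            .reset_index(drop=True)
        )


@dataclass
class ReferenceSet:
    """Named reference driver list (e.g. gold-standard gene census)."""

    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.members = frozenset(self.members)
        if not self.members:
            raise ValueError("reference set is empty")


def read_calls(path: str, method: str) -> CallSet:
    """Read `cohort<TAB>element_id[<TAB>n_samples]` call records."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    df.columns = ["cohort", "element_id", "n_samples"][: df.shape[1]]
    if "n_samples" not in df:
        df["n_samples"] = np.nan
    df["n_samples"] = df["n_samples"].astype(float)
    return CallSet(method, df)


def read_reference(path: str, name: str) -> ReferenceSet:
    with open(path) as fh:
        members = {ln.strip().split("\t")[-1] for ln in fh if ln.strip()}
    return ReferenceSet(name, members)


def filter_recurrence(calls: CallSet, min_samples: int = 3) -> CallSet:
    """Drop candidates mutated in fewer than ``min_samples`` samples."""
    keep = calls.calls["n_samples"].fillna(np.inf) >= min_samples
    return CallSet(calls.method, calls.calls[keep].reset_index(drop=True))


def _metrics_from_counts(tp: int, fp: int, fn: int) -> dict:
    called = tp + fp
    denom = tp + fn
    precision = tp / called if called else float("nan")
    recall = tp / denom if denom else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = 0.0 if tp == 0 and (called or denom) else float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "precision": precision, "recall": recall, "F1": f1,
        "TP": tp, "FP": fp, "FN": fn,
    }


def _pooled_metrics(
    per_cohort_tp: dict[str, dict[str, set]],
    per_cohort_calls: dict[str, dict[str, set]],
    per_cohort_denominator: dict[str, set],
    pooling: str,
) -> pd.DataFrame:
    methods = sorted({m for d in per_cohort_calls.values() for m in d})
    rows = {}
    for m in methods:
        counts = []
        for cohort, denom in per_cohort_denominator.items():
            tp = per_cohort_tp[cohort].get(m, set())
            called = per_cohort_calls[cohort].get(m, set())
            counts.append(
                (len(tp), len(called) - len(tp), len(denom - tp))
            )
        if pooling == "micro":
            tp, fp, fn = (sum(c[i] for c in counts) for i in range(3))
            rows[m] = _metrics_from_counts(tp, fp, fn)
        elif pooling == "macro":
            per = [_metrics_from_counts(*c) for c in counts]
            rows[m] = {
                k: float(np.nanmean([p[k] for p in per]))
                for k in ("precision", "recall", "F1")
            }
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("method")


def coding_benchmark(
    callsets: list[CallSet], gold: ReferenceSet, pooling: str = "micro"
) -> pd.DataFrame:
    """Precision / lower-bound recall / F1 against a gold-standard list.

    True positives are calls present in ``gold``; the recall denominator
    per cohort is the union of every method's true positives there.
    Call sets should be recurrence-filtered first.
    """
    cohorts = sorted({c for cs in callsets for c in cs.calls["cohort"]})
    per_tp: dict[str, dict[str, set]] = {}
    per_calls: dict[str, dict[str, set]] = {}
    per_denom: dict[str, set] = {}
    for cohort in cohorts:
        per_tp[cohort] = {}
        per_calls[cohort] = {}
        union_tp: set = set()
        for cs in callsets:
            called = set(
                cs.calls.loc[cs.calls["cohort"] == cohort, "element_id"]
            )
            tp = called & gold.members
            per_calls[cohort][cs.method] = called
            per_tp[cohort][cs.method] = tp
            union_tp |= tp
        per_denom[cohort] = union_tp
    return _pooled_metrics(per_tp, per_calls, per_denom, pooling)


def consensus_benchmark(
    callsets: list[CallSet], agreement_k: int = 3, pooling: str = "micro"
) -> pd.DataFrame:
    """Benchmark without a gold standard: truth = elements called by
    at least ``agreement_k`` methods in the same cohort."""
    cohorts = sorted({c for cs in callsets for c in cs.calls["cohort"]})
    per_tp: dict[str, dict[str, set]] = {}
    per_calls: dict[str, dict[str, set]] = {}
    per_denom: dict[str, set] = {}
    for cohort in cohorts:
        calls_by_method = {
            cs.method: set(
                cs.calls.loc[cs.calls["cohort"] == cohort, "element_id"]
            )
            for cs in callsets
        }
        votes: dict[str, int] = {}
        for called in calls_by_method.values():
            for e in called:
                votes[e] = votes.get(e, 0) + 1
        truth = {e for e, v in votes.items() if v >= agreement_k}
        per_calls[cohort] = calls_by_method
        per_tp[cohort] = {
            m: called & truth for m, called in calls_by_method.items()
        }
        per_denom[cohort] = truth
    return _pooled_metrics(per_tp, per_calls, per_denom, pooling)
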