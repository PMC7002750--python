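"""Functional impact: phred-like rank transform and per-element scores.

Raw per-mutation scores from external scoring schemes (CADD/DANN-style)
are converted cohort-wide to phred-like scores, -10*log10(rank / N_m),
where rank 1 is the most impactful of the N_m scored mutations.  Each
element's score S under a scheme is the mean over its mutated donors of the
donor's mean phred score, and the functional weight w averages S / S_T
over available schemes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "phred_rank_transform",
    "element_functional_scores",
    "combine_schemes",
    "threshold_score",
    "read_raw_scores",
    "score_elements",
]

SCORE_COLUMNS = ["chrom", "pos0", "ref", "alt", "scheme", "raw_score"]


def phred_rank_transform(raw: np.ndarray | pd.Series) -> np.ndarray:
    """Convert raw scores of one scheme to phred-like scores by rank.

    Higher raw score means more impactful: the top score gets rank 1 and
    phred -10*log10(1/N_m); the bottom score gets phred 0.  Ties share the
    average of their ranks.
    """
    vals = np.asarray(raw, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot rank an empty score vector")
    ranks = rankdata(-vals, method="average")
    return -10.0 * np.log10(ranks / vals.size)


def threshold_score(F: float) -> float:
    """S_T = -10*log10(F): the phred score of the top F fraction boundary."""
    if not 0.0 < F < 1.0:
        raise ValueError("F must lie in (0, 1)")
    return -10.0 * np.log10(F)


def read_raw_scores(path: str) -> pd.DataFrame:
    """Read per-mutation raw scores: chrom pos0 ref alt scheme raw_score."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    has_header = not str(first.iloc[0, 1]).lstrip("-").isdigit()
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=SCORE_COLUMNS,
        dtype={"chrom": str, "ref": str, "alt": str, "scheme": str},
    )
    df["pos0"] = df["pos0"].astype(np.int64)
    df["raw_score"] = df["raw_score"].astype(float)
    return df


def element_functional_scores(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-element, per-scheme functional score S.

    ``scored`` has one row per (mutation, scheme) with columns element_id,
    donor_id, scheme and phred.  For each element and scheme, the donor
    score s_i is the mean phred of donor i's scored mutations in the
    element and S is the mean of s_i over donors contributing at least one
    scored mutation.  Returns a DataFrame element_id x scheme (NaN where a
    scheme scored no mutation of the element).
    """
    donor_means = (
        scored.groupby(["element_id", "scheme", "donor_id"], sort=False)[
            "phred"
        ].mean()
    )
    S = donor_means.groupby(["element_id", "scheme"]).mean()
    return S.unstack("scheme")


def combine_schemes(impacts: pd.Series | dict, S_T: float) -> float:
    """Combined functional weight: mean over available schemes of S / S_T."""
    if S_T <= 0:
        raise ValueError("S_T must be positive")
    vals = pd.Series(impacts, dtype=float).dropna()
    if vals.empty:
        raise ValueError("no scheme with a defined score")
    return float((vals / S_T).mean())


def score_elements(
    raw_scores: pd.DataFrame,
    mutation_hits: pd.DataFrame,
    S_T: float,
) -> pd.DataFrame:
    """Full scoring path: rank-transform each scheme cohort-wide, attach
    mutations to elements, and return per-element S per scheme plus the
    combined weight.

    ``raw_scores``: chrom/pos0/ref/alt/scheme/raw_score over all observed,
    scored mutations in the data set (the ranking universe is cohort-wide,
    per scheme).  ``mutation_hits``: one row per (mutation, element) with
    chrom/pos0/ref/alt/donor_id/element_id.  Elements with no scored
    mutation under any scheme get weight NaN (callers treat that as a
    neutral w = 1).
    """
    scored = raw_scores.copy()
    scored["phred"] = np.nan
    for scheme, grp in scored.groupby("scheme"):
        scored.loc[grp.index, "phred"] = phred_rank_transform(
            grp["raw_score"].to_numpy()
        )
    keys = ["chrom", "pos0", "ref", "alt"]
    merged = mutation_hits.merge(
        scored[keys + ["scheme", "phred"]], on=keys, how="inner"
    )
    if merged.empty:
        return pd.DataFrame(columns=["combined_weight"]).rename_axis(
            "element_id"
        )
    S = element_functional_scores(merged)
    S["combined_weight"] = (S / S_T).mean(axis=1, skipna=True)
    return S
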