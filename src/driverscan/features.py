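"""Per-element covariate features: nucleotide content, track signal, overlaps.

Three feature families are computed per element: k-mer fractions of the
element sequence (k = 2, 3), mean signal of genome-wide tracks over covered
bases, and the fraction of element bases intersecting peak sets.  Missing
values are imputed with 0 and, for the lasso/GLM path only, features are
robust-scaled (median/IQR fit on training elements).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import RobustScaler

from .elements import ElementSet, GenomicElement, RegionMask, intersect_length

__all__ = [
    "kmer_fractions",
    "mean_track_signal",
    "overlap_fraction",
    "TsvTrack",
    "BigWigTrack",
    "build_feature_matrix",
    "impute_and_scale",
    "ScalingStats",
    "read_feature_matrix",
    "write_feature_matrix",
]

_BASES = "ACGT"


def all_kmers(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(_BASES, repeat=k)]


def kmer_fractions(element_sequence, k: int) -> pd.Series:
    """Fractions of overlapping k-mers (k = 2 or 3) in an element sequence.

    ``element_sequence`` may be a single string or a list of per-interval
    strings; windows never span interval junctions and windows containing N
    are skipped.  Returns all-NaN when no valid window exists.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    seqs = (
        [element_sequence]
        if isinstance(element_sequence, str)
        else list(element_sequence)
    )
    counts = dict.fromkeys(all_kmers(k), 0)
    total = 0
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            mer = seq[i : i + k]
            if mer in counts:
                counts[mer] += 1
                total += 1
    idx = pd.Index(all_kmers(k))
    if total == 0:
        return pd.Series(np.nan, index=idx)
    return pd.Series(counts, dtype=float).reindex(idx) / total


# ---------------------------------------------------------------------------
# track access: a common interval-query interface with TSV and bigWig backends
# ---------------------------------------------------------------------------

class TsvTrack:
    """Per-base signal defined by (chrom, start, end, value) TSV records.

    Bases outside any record are uncovered.  This plain-text dialect lets the
    full feature path run without binary track files.
    """

    def __init__(self, path_or_df):
        df = (
            path_or_df
            if isinstance(path_or_df, pd.DataFrame)
            else pd.read_csv(
                path_or_df,
                sep="\t",
                header=None,
                names=["chrom", "start", "end", "value"],
                comment="#",
            )
        )
        self._by_chrom = {
            str(c): g.sort_values("start")[["start", "end", "value"]]
            .to_numpy(dtype=float)
            for c, g in df.groupby("chrom")
        }

    def stats(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """Return (sum of signal over covered bases, covered bp) in [start, end)."""
        arr = self._by_chrom.get(chrom)
        if arr is None:
            return 0.0, 0
        total = 0.0
        covered = 0
        for s, e, v in arr:
            lo, hi = max(start, int(s)), min(end, int(e))
            if lo < hi:
                total += v * (hi - lo)
                covered += hi - lo
        return total, covered


class BigWigTrack:
    """bigWig-backed signal source (requires pyBigWig)."""

    def __init__(self, path: str):
        import pyBigWig  # deferred: binary backend is optional

        self._bw = pyBigWig.open(path)

    def stats(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        vals = self._bw.values(chrom, start, end, numpy=True)
        ok = ~np.isnan(vals)
        return float(np.nansum(vals)), int(ok.sum())


def mean_track_signal(element: GenomicElement, track) -> float:
    """Mean track signal over the covered bases of an element.

    Uncovered bases are excluded from the denominator; NaN when the track
    covers no base of the element.
    """
    total = 0.0
    covered = 0
    for chrom, ivs in element.masked_intervals.items():
        for s, e in ivs:
            t, c = track.stats(chrom, s, e)
            total += t
            covered += c
    return total / covered if covered else float("nan")


def overlap_fraction(element: GenomicElement, peaks: RegionMask) -> float:
    """Fraction of the element's effective bases that fall inside peaks."""
    L = element.effective_length
    if L == 0:
        raise ValueError(f"element {element.element_id} has no usable base")
    bp = sum(
        intersect_length(ivs, peaks.intervals.get(chrom, []))
        for chrom, ivs in element.masked_intervals.items()
    )
    return bp / L


# ---------------------------------------------------------------------------
# feature matrix assembly and scaling
# ---------------------------------------------------------------------------

def element_sequences(element: GenomicElement, fasta) -> list[str]:
    """Fetch per-interval sequences (masked intervals, genomic order)."""
    seqs = []
    for chrom in sorted(element.masked_intervals):
        for s, e in element.masked_intervals[chrom]:
            seqs.append(str(fasta[chrom][s:e]))
    return seqs


def build_feature_matrix(
    elements: ElementSet,
    fasta=None,
    tracks: dict[str, object] | None = None,
    peaks: dict[str, RegionMask] | None = None,
    ks: tuple[int, ...] = (2, 3),
) -> pd.DataFrame:
    """Assemble the raw (unimputed, unscaled) element x feature matrix.

    Columns: k-mer fractions (when a FASTA is given), one ``mean_<name>``
    per track and one ``frac_<name>`` per peak set.  Untestable elements
    (effective length 0) get all-NaN rows.
    """
    rows = {}
    kmer_cols = [m for k in ks for m in all_kmers(k)] if fasta is not None else []
    for e in elements:
        feats: dict[str, float] = {}
        if fasta is not None:
            seqs = element_sequences(e, fasta) if not e.untestable else []
            for k in ks:
                feats.update(kmer_fractions(seqs, k).to_dict())
        for name, track in (tracks or {}).items():
            feats[f"mean_{name}"] = (
                mean_track_signal(e, track) if not e.untestable else np.nan
            )
        for name, pk in (peaks or {}).items():
            feats[f"frac_{name}"] = (
                overlap_fraction(e, pk) if not e.untestable else np.nan
            )
        rows[e.element_id] = feats
    cols = kmer_cols + [f"mean_{n}" for n in (tracks or {})] + [
        f"frac_{n}" for n in (peaks or {})
    ]
    X = pd.DataFrame.from_dict(rows, orient="index")
    return X.reindex(columns=cols) if cols else X


@dataclass
class ScalingStats:
    """Per-feature robust-scaling statistics fit on training rows."""

    center: pd.Series  # median
    spread: pd.Series  # IQR (Q3 - Q1), zeros replaced by 1

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "ScalingStats":
        scaler = RobustScaler().fit(X.to_numpy(dtype=float))
        return cls(
            center=pd.Series(scaler.center_, index=X.columns),
            spread=pd.Series(scaler.scale_, index=X.columns),
        )


def impute_and_scale(
    X: pd.DataFrame, stats: ScalingStats | None = None
) -> tuple[pd.DataFrame, ScalingStats]:
    """Zero-impute missing values, then center by median and divide by IQR.

    When ``stats`` is None the statistics are fit on these rows (training
    path); otherwise the given (training-fitted) statistics transform the
    rows.  Constant features (IQR 0) are left centered but undivided.
    """
    filled = X.fillna(0.0)
    if stats is None:
        stats = ScalingStats.fit(filled)
    elif not stats.center.index.equals(X.columns):
        raise ValueError("feature names of X do not match scaling stats")
    scaled = (filled - stats.center) / stats.spread
    return scaled, stats


def impute(X: pd.DataFrame) -> pd.DataFrame:
    """Zero-impute only (the GBM path consumes unscaled features)."""
    return X.fillna(0.0)


def write_feature_matrix(X: pd.DataFrame, path: str) -> None:
    """TSV by default; a parquet binary cache when the path ends .parquet."""
    if str(path).endswith(".parquet"):
        X.rename_axis("element_id").to_parquet(path)
        return
    X.to_csv(path, sep="\t", index_label="element_id")


def read_feature_matrix(path: str) -> pd.DataFrame:
    if str(path).endswith(".parquet"):  # binary cache
        return pd.read_parquet(path)
    return pd.read_csv(path, sep="\t", index_col="element_id")
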