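"""Genomic elements: BED I/O, masking, binning and training-element sampling.

A *genomic element* is a named union of intervals defining one functional
unit (e.g. all coding exons of a gene, a promoter window).  All coordinates
are 0-based half-open (BED convention).  Excluded-region masks are
subtracted from elements before any counting or feature computation; the
remaining bases define the element's effective length L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GenomicElement",
    "ElementSet",
    "RegionMask",
    "load_elements",
    "load_mask",
    "read_chrom_sizes",
    "write_elements",
    "apply_mask",
    "make_fixed_bins",
    "sample_training_elements",
    "merge_intervals",
    "subtract_intervals",
    "intersect_length",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# low-level interval arithmetic on sorted (start, end) arrays, one chromosome
# ---------------------------------------------------------------------------

def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping intervals into a sorted disjoint list."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_intervals(
    ivs: list[tuple[int, int]], sub: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Subtract merged `sub` from merged `ivs` (both sorted, disjoint)."""
    if not sub or not ivs:
        return list(ivs)
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in ivs:
        cur = s
        while j > 0 and sub[j - 1][1] > cur:
            j -= 1
        k = j
        while k < len(sub) and sub[k][0] < e:
            ms, me = sub[k]
            if ms > cur:
                out.append((cur, min(ms, e)))
            cur = max(cur, me)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_length(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> int:
    """Total overlap in bp between two merged, sorted interval lists."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass
class GenomicElement:
    """Named union of genomic intervals with raw and mask-subtracted length."""

    element_id: str
    intervals: dict[str, list[tuple[int, int]]]  # chrom -> merged intervals
    masked_intervals: dict[str, list[tuple[int, int]]] | None = None

    def __post_init__(self) -> None:
        self.intervals = {
            c: merge_intervals(ivs) for c, ivs in self.intervals.items() if ivs
        }
        if self.masked_intervals is None:
            self.masked_intervals = {
                c: list(ivs) for c, ivs in self.intervals.items()
            }

    @property
    def raw_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    @property
    def effective_length(self) -> int:
        return sum(
            e - s for ivs in self.masked_intervals.values() for s, e in ivs
        )

    @property
    def untestable(self) -> bool:
        """True when masking removed every base of the element."""
        return self.effective_length == 0


@dataclass
class ElementSet:
    """Collection of uniquely named elements (e.g. CDS, 5'UTR, training)."""

    name: str
    elements: dict[str, GenomicElement] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements.values())

    def __getitem__(self, element_id: str) -> GenomicElement:
        return self.elements[element_id]

    def add(self, element: GenomicElement) -> None:
        if element.element_id in self.elements:
            raise ValueError(f"duplicate element_id {element.element_id!r}")
        self.elements[element.element_id] = element

    def effective_lengths(self) -> pd.Series:
        return pd.Series(
            {e.element_id: e.effective_length for e in self}, name="L"
        )


@dataclass
class RegionMask:
    """Merged interval set marking excluded (or callable) genome regions."""

    intervals: dict[str, list[tuple[int, int]]]
    polarity: str = "excluded"  # or "callable"

    def __post_init__(self) -> None:
        if self.polarity not in ("excluded", "callable"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        self.intervals = {
            c: merge_intervals(ivs) for c, ivs in self.intervals.items() if ivs
        }

    @classmethod
    def empty(cls, polarity: str = "excluded") -> "RegionMask":
        return cls({}, polarity)

    def total_bp(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        starts = [s for s, _ in ivs]
        i = np.searchsorted(starts, pos, side="right") - 1
        return i >= 0 and ivs[i][1] > pos


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int) -> list[tuple[str, int, int, str]]:
    """Return (chrom, start, end, name) records for one BED4/BED12 line."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"line {lineno}: expected >=3 BED columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as err:
        raise ValueError(f"line {lineno}: non-integer coordinates") from err
    if end <= start or start < 0:
        raise ValueError(f"line {lineno}: end <= start ({start}, {end})")
    name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
    if len(fields) >= 12:  # BED12: expand blocks
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise ValueError(f"line {lineno}: malformed BED12 blocks")
        return [
            (chrom, start + o, start + o + sz, name)
            for o, sz in zip(offsets, sizes)
        ]
    return [(chrom, start, end, name)]


def load_elements(path: str, name: str) -> ElementSet:
    """Read a BED4 (one interval per record) or BED12 file into an ElementSet.

    Records sharing column-4 names are grouped into one element and their
    intervals merged.
    """
    grouped: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            for chrom, start, end, eid in _parse_bed_line(line, lineno):
                grouped.setdefault(eid, {}).setdefault(chrom, []).append(
                    (start, end)
                )
    out = ElementSet(name)
    for eid, ivs in grouped.items():
        out.add(GenomicElement(eid, ivs))
    return out


def load_mask(path: str, polarity: str = "excluded") -> RegionMask:
    """Read a BED3 file into a merged RegionMask."""
    ivs: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, _ = _parse_bed_line(line, lineno)[0]
            ivs.setdefault(chrom, []).append((start, end))
    return RegionMask(ivs, polarity)


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a UCSC-style two-column .chrom.sizes TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_elements(elements: ElementSet, path: str) -> None:
    """Write an ElementSet as BED4, one line per interval."""
    with open(path, "w") as fh:
        for e in elements:
            for chrom in sorted(e.intervals):
                for s, t in e.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{t}\t{e.element_id}\n")


# ---------------------------------------------------------------------------
# masking, binning, sampling
# ---------------------------------------------------------------------------

def apply_mask(elements: ElementSet, mask: RegionMask) -> ElementSet:
    """Subtract an excluded-region mask from every element.

    Returns a new ElementSet whose elements carry mask-subtracted
    ``masked_intervals`` and hence updated effective lengths.  Elements whose
    every base is excluded are retained but flagged ``untestable``.
    Idempotent: applying the same mask twice equals applying it once.
    """
    if mask.polarity != "excluded":
        raise ValueError("apply_mask expects an excluded-polarity mask")
    out = ElementSet(elements.name)
    for e in elements:
        masked = {}
        for chrom, ivs in e.intervals.items():
            rem = subtract_intervals(ivs, mask.intervals.get(chrom, []))
            if rem:
                masked[chrom] = rem
        out.add(GenomicElement(e.element_id, e.intervals, masked))
    return out


def make_fixed_bins(
    chrom_sizes: dict[str, int], width: int, chrom_filter=None
) -> ElementSet:
    """Tile chromosomes with consecutive fixed-width bins.

    Trailing partial bins are dropped, so every bin has length exactly
    ``width`` (the convention used for whole-genome megabase bins).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    out = ElementSet(f"bins_{width}")
    for chrom in sorted(chrom_sizes):
        if chrom_filter is not None and not chrom_filter(chrom):
            continue
        for k in range(chrom_sizes[chrom] // width):
            s = k * width
            out.add(GenomicElement(f"{chrom}.bin{k}", {chrom: [(s, s + width)]}))
    return out


def sample_training_elements(
    test_sets: list[ElementSet],
    callable_mask: RegionMask,
    n: int,
    length_factor: float = 3.0,
    seed: int = 0,
    max_tries_per_element: int = 100,
) -> ElementSet:
    """Randomly sample background (training) elements from callable space.

    Lengths are drawn with replacement from the pooled raw-length
    distribution of the test elements and multiplied by ``length_factor``.
    Chromosomes are drawn with probability proportional to callable bp; a
    uniform start is drawn within callable runs long enough to hold the
    element; candidates overlapping any test-element base are rejected and
    redrawn.  Deterministic under ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if callable_mask.polarity != "callable":
        raise ValueError("sampling requires a callable-polarity mask")
    pooled = [e.raw_length for es in test_sets for e in es]
    if not pooled:
        raise ValueError("pooled test-element length distribution is empty")
    rng = np.random.default_rng(seed)

    test_ivs: dict[str, list[tuple[int, int]]] = {}
    for es in test_sets:
        for e in es:
            for chrom, ivs in e.intervals.items():
                test_ivs.setdefault(chrom, []).extend(ivs)
    test_ivs = {c: merge_intervals(v) for c, v in test_ivs.items()}

    runs = {
        c: [(s, t) for s, t in ivs]
        for c, ivs in callable_mask.intervals.items()
    }
    chroms = sorted(runs)
    chrom_bp = np.array(
        [sum(t - s for s, t in runs[c]) for c in chroms], dtype=float
    )
    if chrom_bp.sum() == 0:
        raise RuntimeError("callable space is empty")
    chrom_p = chrom_bp / chrom_bp.sum()

    out = ElementSet("training")
    budget = max_tries_per_element * n
    tries = 0
    i = 0
    while len(out) < n:
        if tries >= budget:
            raise RuntimeError(
                f"training-element sampling exhausted retry budget ({budget})"
            )
        tries += 1
        length = int(round(length_factor * pooled[rng.integers(len(pooled))]))
        length = max(length, 1)
        chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
        fits = [(s, t) for s, t in runs[chrom] if t - s >= length]
        if not fits:
            continue
        # run chosen with probability proportional to its number of valid
        # starts, then a uniform start inside it: uniform over all placements
        weights = np.array([t - s - length + 1 for s, t in fits], dtype=float)
        run_i = rng.choice(len(fits), p=weights / weights.sum())
        rs, rt = fits[run_i]
        start = int(rng.integers(rs, rt - length + 1))
        end = start + length
        if intersect_length(
            [(start, end)], test_ivs.get(chrom, [])
        ):
            continue
        out.add(GenomicElement(f"train_{i}", {chrom: [(start, end)]}))
        i += 1
    return out
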