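"""Synthetic cohort generator with known ground truth.

Emulates the inputs of a whole-genome driver scan — element coordinates,
a per-element covariate matrix, a somatic mutation catalog and raw
functional scores — from a fully specified generative model, so every
stage of the framework is testable without external data.

Default conditions describe a moderately-to-highly mutated adult solid
tumour cohort: 200 donors at a baseline of 10 mutations/Mb/donor, 5000
test and 5000 background (training) elements with lognormal lengths
(median 3 kb), and ten standard-normal covariates whose log-rate effects
span the few-fold background variation real covariates explain.  Counts
are Poisson, or NB2 (variance mu + theta*mu^2) when ``theta_true`` > 0.
Spiked driver elements have their rate multiplied by a fold change and
their mutations' raw functional scores shifted upward on the raw-score
scale, so the rank transform is exercised honestly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import ElementSet, GenomicElement
from .bmr import MUTATION_COLUMNS

__all__ = ["SimConfig", "SimulatedCohort", "simulate_cohort", "pick_drivers"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    n_elements: int = 5000
    n_train: int = 5000
    n_donors: int = 200
    length_log_median: float = np.log(3000.0)
    length_log_sd: float = 0.4
    rate_per_donor_bp: float = 1e-5  # 10 mutations/Mb/donor baseline
    n_features: int = 10
    effects: tuple = (0.15, -0.15, 0.10, -0.10, 0.05, -0.05, 0.02, -0.02, 0.0, 0.0)
    theta_true: float = 0.0
    drivers: tuple = ()  # (element_index, rate_fold, score_shift_sd)
    schemes: tuple = ("scheme_a", "scheme_b")
    scheme_sd: float = 1.0
    element_gap: int = 1000
    seed: int = 0

    def __post_init__(self):
        if len(self.effects) != self.n_features:
            raise ValueError("effects length must equal n_features")
        if self.theta_true < 0:
            raise ValueError("theta_true must be >= 0")
        for idx, fold, _ in self.drivers:
            if not 0 <= idx < self.n_elements:
                raise ValueError(f"driver index {idx} out of range")
            if fold <= 1:
                raise ValueError("driver fold change must exceed 1")


def pick_drivers(
    cfg: SimConfig, n_drivers: int, fold: float, shift_sd: float, seed: int
) -> SimConfig:
    """Return a config with ``n_drivers`` randomly chosen spiked elements."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(cfg.n_elements, size=n_drivers, replace=False)
    drivers = tuple((int(i), float(fold), float(shift_sd)) for i in sorted(idx))
    return SimConfig(**{**asdict(cfg), "drivers": drivers})


@dataclass
class SimulatedCohort:
    config: SimConfig
    test_elements: ElementSet
    train_elements: ElementSet
    X_test: pd.DataFrame
    X_train: pd.DataFrame
    mutations: pd.DataFrame
    raw_scores: pd.DataFrame
    truth: dict = field(repr=False)

    @property
    def n_donors(self) -> int:
        return self.config.n_donors

    def write(self, outdir: str) -> None:
        """Emit the exact text dialects the rest of the framework consumes."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        from .elements import write_elements
        from .features import write_feature_matrix

        write_elements(self.test_elements, out / "test_elements.bed")
        write_elements(self.train_elements, out / "train_elements.bed")
        self.mutations[MUTATION_COLUMNS].to_csv(
            out / "mutations.tsv", sep="\t", index=False
        )
        write_feature_matrix(self.X_test, out / "features_test.tsv")
        write_feature_matrix(self.X_train, out / "features_train.tsv")
        self.raw_scores.to_csv(out / "raw_scores.tsv", sep="\t", index=False)
        with open(out / "donors.txt", "w") as fh:
            for d in self.truth["donors"]:
                fh.write(d + "\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=float)


def _place_elements(
    prefix: str, chrom: str, lengths: np.ndarray, gap: int
) -> ElementSet:
    es = ElementSet(prefix)
    pos = 0
    for i, length in enumerate(lengths):
        es.add(
            GenomicElement(f"{prefix}_{i}", {chrom: [(pos, pos + int(length))]})
        )
        pos += int(length) + gap
    return es


def simulate_cohort(cfg: SimConfig | None = None) -> SimulatedCohort:
    """Generate one cohort; byte-deterministic under ``cfg.seed``."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n_all = cfg.n_elements + cfg.n_train
    lengths = np.maximum(
        np.round(
            np.exp(rng.normal(cfg.length_log_median, cfg.length_log_sd, n_all))
        ).astype(int),
        50,
    )
    test_es = _place_elements("test", "chr1", lengths[: cfg.n_elements], cfg.element_gap)
    train_es = _place_elements("train", "chr2", lengths[cfg.n_elements:], cfg.element_gap)

    X = rng.normal(size=(n_all, cfg.n_features))
    feature_names = [f"f{j}" for j in range(cfg.n_features)]
    ids = [f"test_{i}" for i in range(cfg.n_elements)] + [
        f"train_{i}" for i in range(cfg.n_train)
    ]
    Xdf = pd.DataFrame(X, index=pd.Index(ids, name="element_id"), columns=feature_names)

    effects = np.asarray(cfg.effects, dtype=float)
    lam = (
        cfg.n_donors
        * lengths.astype(float)
        * cfg.rate_per_donor_bp
        * np.exp(X @ effects)
    )
    driver_fold = np.ones(n_all)
    driver_shift = np.zeros(n_all)
    for idx, fold, shift in cfg.drivers:
        driver_fold[idx] = fold
        driver_shift[idx] = shift
    lam_spiked = lam * driver_fold
    if cfg.theta_true > 0:
        mix = rng.gamma(1.0 / cfg.theta_true, cfg.theta_true, size=n_all)
        y = rng.poisson(lam_spiked * mix)
    else:
        y = rng.poisson(lam_spiked)

    donors = np.array([f"donor_{i:04d}" for i in range(cfg.n_donors)])
    all_elements = list(test_es) + list(train_es)
    starts = np.array(
        [next(iter(e.intervals.values()))[0][0] for e in all_elements]
    )
    widths = np.array([e.raw_length for e in all_elements])
    elem_idx = np.repeat(np.arange(n_all), y)
    total = int(y.sum())
    pos = starts[elem_idx] + rng.integers(0, widths[elem_idx])  # dup sites ok
    didx = rng.integers(0, cfg.n_donors, size=total)
    ref_i = rng.integers(0, 4, size=total)
    alt_i = (ref_i + rng.integers(1, 4, size=total)) % 4  # always != ref
    chrom = np.where(elem_idx < cfg.n_elements, "chr1", "chr2")
    muts = pd.DataFrame(
        {
            "chrom": chrom,
            "pos0": pos,
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
            "donor_id": donors[didx],
            "_element_index": elem_idx,
        }
    )

    # raw functional scores: one row per (mutation, scheme); spiked
    # elements' mutations are shifted on the raw-score scale
    shift = driver_shift[muts["_element_index"].to_numpy()] * cfg.scheme_sd
    score_frames = []
    for scheme in cfg.schemes:
        raw = rng.normal(0.0, cfg.scheme_sd, size=len(muts)) + shift
        sf = muts[["chrom", "pos0", "ref", "alt"]].copy()
        sf["scheme"] = scheme
        sf["raw_score"] = raw
        score_frames.append(sf)
    raw_scores = (
        pd.concat(score_frames, ignore_index=True)
        if score_frames
        else pd.DataFrame(columns=["chrom", "pos0", "ref", "alt", "scheme", "raw_score"])
    )
    # duplicate sites would make (chrom,pos,ref,alt) ambiguous across rows;
    # keep the first score per site+scheme so joins are well defined
    raw_scores = raw_scores.drop_duplicates(
        subset=["chrom", "pos0", "ref", "alt", "scheme"], keep="first"
    ).reset_index(drop=True)

    truth = {
        "config": asdict(cfg),
        "donors": donors.tolist(),
        "element_ids": ids,
        "lengths": lengths.tolist(),
        "lambda_background": lam.tolist(),
        "lambda_spiked": lam_spiked.tolist(),
        "y": y.tolist(),
        "drivers": [list(d) for d in cfg.drivers],
    }
    return SimulatedCohort(
        cfg,
        test_es,
        train_es,
        Xdf.iloc[: cfg.n_elements],
        Xdf.iloc[cfg.n_elements:],
        muts.drop(columns="_element_index"),
        raw_scores,
        truth,
    )


def write_sequence_fixture(
    chrom_sizes: dict[str, int], outdir: str, seed: int = 0
) -> dict[str, str]:
    """Write a small random FASTA, a signal-track TSV and a peaks BED.

    Only intended for toy genomes (guarded at 2 Mb total): provides the
    inputs the feature builder needs without any binary file.
    """
    total = sum(chrom_sizes.values())
    if total > 2_000_000:
        raise ValueError("sequence fixture limited to 2 Mb total")
    rng = np.random.default_rng(seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, size in chrom_sizes.items():
            seq = "".join(_BASES[rng.integers(0, 4, size=size)])
            fh.write(f">{chrom}\n")
            for i in range(0, size, 80):
                fh.write(seq[i : i + 80] + "\n")
    track = out / "track.tsv"
    with open(track, "w") as fh:
        for chrom, size in chrom_sizes.items():
            pos = 0
            while pos < size:
                w = int(rng.integers(200, 1000))
                if rng.random() < 0.8:  # 20% coverage gaps
                    fh.write(
                        f"{chrom}\t{pos}\t{min(pos + w, size)}\t"
                        f"{rng.normal(1.0, 0.3):.4f}\n"
                    )
                pos += w
    peaks = out / "peaks.bed"
    with open(peaks, "w") as fh:
        for chrom, size in chrom_sizes.items():
            for _ in range(max(size // 5000, 1)):
                s = int(rng.integers(0, max(size - 500, 1)))
                fh.write(f"{chrom}\t{s}\t{min(s + 400, size)}\n")
    return {"fasta": str(fasta), "track": str(track), "peaks": str(peaks)}
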