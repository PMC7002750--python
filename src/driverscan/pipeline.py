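"""End-to-end driver inference: the five-step outline as one library call.

Steps: (1) mask elements and scale features; (2) fit the background
mutation rate model on training elements; (3) burden-test the observed
counts of test elements and BH-correct; (4) re-weight the counts of nearly
significant elements by their functional impact; (5) re-test and
BH-correct at cohort and global scope.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .elements import ElementSet, RegionMask, apply_mask
from .features import impute, impute_and_scale
from .bmr import (
    GBMConfig,
    MutationCatalog,
    assign_mutations,
    count_mutations,
    fit_binomial_glm,
    fit_gbm,
    predict_expected,
    select_features_randomized_lasso,
)
from .impact import score_elements
from .significance import (
    AdjustmentConfig,
    DispersionEstimate,
    run_significance,
    overdispersion_test,
)

__all__ = ["RunConfig", "InferenceResult", "infer_cohort", "seed_stream"]


def seed_stream(root_seed: int, name: str) -> int:
    """Derive a named child seed (< 2^31) from one root seed."""
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated configuration for one inference run."""

    cohort: str = "cohort"
    element_set: str = "all"
    model: str = "gbm"  # "glm" | "gbm"
    lymphoma: bool = False  # triples the dispersion scaling s
    F: float = 0.01
    q_gate: float = 0.25
    q_sig: float = 0.1
    od_cut: float = 0.01
    hypermutator_cutoff: float | None = 30.0
    lasso_repeats: int = 500
    gbm: GBMConfig = field(default_factory=GBMConfig)
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("glm", "gbm"):
            raise ValueError(f"unknown model kind {self.model!r}")
        AdjustmentConfig(self.F, self.q_gate, self.q_sig, self.od_cut)

    @property
    def dispersion_scale(self) -> float:
        return 3.0 if self.lymphoma else 1.0

    def adjustment(self) -> AdjustmentConfig:
        return AdjustmentConfig(self.F, self.q_gate, self.q_sig, self.od_cut)


@dataclass
class InferenceResult:
    results: pd.DataFrame
    untestable: list[str]
    dispersion: DispersionEstimate
    catalog_test: MutationCatalog
    catalog_train: MutationCatalog
    prediction: pd.Series
    selection: object | None
    manifest: dict

    def write(self, outdir: str) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(
            out / "results.tsv", sep="\t", index=False, float_format="%.6g"
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)


def infer_cohort(
    test_elements: ElementSet,
    train_elements: ElementSet,
    mutations: pd.DataFrame,
    X_test: pd.DataFrame,
    X_train: pd.DataFrame,
    config: RunConfig | None = None,
    mask: RegionMask | None = None,
    raw_scores: pd.DataFrame | None = None,
    donors: list[str] | None = None,
    genome_bp: float | None = None,
) -> InferenceResult:
    """Run the full driver scan for one cohort.

    Feature matrices are raw (unimputed) element x feature tables indexed
    by element_id; ``raw_scores`` holds per-mutation raw functional scores
    per scheme (optional: without it no functional adjustment is applied,
    all weights stay 1).  ``genome_bp`` (the callable genome size) enables
    the hypermutator donor filter.
    """
    cfg = config or RunConfig()
    if mask is not None:
        test_elements = apply_mask(test_elements, mask)
        train_elements = apply_mask(train_elements, mask)

    cat_test = count_mutations(
        mutations, test_elements, donors=donors, genome_bp=genome_bp,
        hypermutator_cutoff=cfg.hypermutator_cutoff, warn_unknown=False,
    )
    cat_train = count_mutations(
        mutations, train_elements, donors=donors, genome_bp=genome_bp,
        hypermutator_cutoff=cfg.hypermutator_cutoff, warn_unknown=False,
    )

    testable_tr = cat_train.table.index[cat_train.L > 0]
    cat_train_fit = MutationCatalog(
        cat_train.table.loc[testable_tr], cat_train.n_donors
    )
    untestable = list(cat_test.table.index[cat_test.L == 0])
    testable = cat_test.table.index[cat_test.L > 0]
    cat_test_fit = MutationCatalog(
        cat_test.table.loc[testable], cat_test.n_donors
    )

    selection = None
    if cfg.model == "glm":
        Xtr_s, stats = impute_and_scale(X_train.loc[testable_tr])
        Xte_s, _ = impute_and_scale(X_test.loc[testable], stats)
        selection = select_features_randomized_lasso(
            Xtr_s, cat_train_fit, n_repeats=cfg.lasso_repeats,
            seed=seed_stream(cfg.seed, "lasso"),
        )
        chosen = selection.selected or list(X_train.columns)
        model = fit_binomial_glm(Xtr_s[chosen], cat_train_fit)
        yhat_test = predict_expected(
            model, Xte_s, cat_test_fit.L, cat_test_fit.n_donors
        )
        yhat_train = predict_expected(
            model, Xtr_s, cat_train_fit.L, cat_train_fit.n_donors
        )
    else:
        Xtr = impute(X_train.loc[testable_tr])
        Xte = impute(X_test.loc[testable])
        model = fit_gbm(
            Xtr, cat_train_fit, cfg.gbm, seed=seed_stream(cfg.seed, "gbm")
        )
        yhat_test = predict_expected(
            model, Xte, cat_test_fit.L, cat_test_fit.n_donors
        )
        yhat_train = predict_expected(
            model, Xtr, cat_train_fit.L, cat_train_fit.n_donors
        )

    disp = overdispersion_test(
        cat_train_fit.y.to_numpy(), yhat_train.to_numpy(),
        s=cfg.dispersion_scale,
    )

    table = cat_test_fit.table.copy()
    table["element_id"] = table.index
    table["yhat"] = yhat_test
    table["N"] = cat_test_fit.n_donors
    table["cohort"] = cfg.cohort
    table["set"] = cfg.element_set

    acfg = cfg.adjustment()
    if raw_scores is not None and len(raw_scores):
        hits = assign_mutations(mutations, test_elements, warn_unknown=False)
        impacts = score_elements(raw_scores, hits, acfg.S_T)
        table["S_combined"] = np.nan
        table["w"] = np.nan
        if "combined_weight" in impacts:
            common = impacts.index.intersection(table.index)
            table.loc[common, "w"] = impacts.loc[common, "combined_weight"]
            scheme_cols = [c for c in impacts.columns if c != "combined_weight"]
            if scheme_cols:
                table.loc[common, "S_combined"] = impacts.loc[
                    common, scheme_cols
                ].mean(axis=1)

    results = run_significance(table.reset_index(drop=True), disp, acfg)

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(cfg),
        "seed_streams": {
            name: seed_stream(cfg.seed, name) for name in ("lasso", "gbm")
        },
        "n_donors": cat_test.n_donors,
        "excluded_hypermutators": list(cat_test.excluded_donors),
        "n_test_elements": len(cat_test.table),
        "n_untestable": len(untestable),
        "n_train_elements": len(cat_train_fit.table),
        "n_mutations": int(len(mutations)),
        "dispersion": {
            "theta": disp.theta, "p_od": disp.p_od, "s": disp.s,
        },
        "overdispersed_null": bool(
            disp.p_od <= cfg.od_cut and disp.effective_theta > 0
        ),
        "n_significant": int(results["is_significant"].sum()),
        "selected_features": list(selection.selected) if selection else None,
    }
    return InferenceResult(
        results, untestable, disp, cat_test_fit, cat_train_fit,
        yhat_test, selection, manifest,
    )


def input_checksums(paths: dict[str, str]) -> dict[str, str]:
    """sha256 of each input file, recorded in run manifests."""
    out = {}
    for name, path in paths.items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        out[name] = h.hexdigest()
    return out
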