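"""Background mutation rate models: counting, feature selection, GLM and GBM.

The background model estimates, for every genomic element i with feature
vector X_i and effective length L_i, the expected passenger mutation count
yhat_i = E(y_i | X_i, L_i) in a cohort of N donors.  Two models are
provided: a binomial GLM on features chosen by randomised-lasso stability
selection, and gradient-boosted trees with a Poisson likelihood and
ln(N*L) offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xgboost as xgb
from scipy.special import expit, logit
from sklearn.linear_model import Lasso, LassoCV

from .elements import ElementSet, RegionMask

__all__ = [
    "MutationRecord",
    "read_mutations",
    "mutations_from_vcf",
    "count_mutations",
    "MutationCatalog",
    "LassoSelection",
    "select_features_randomized_lasso",
    "GLMModel",
    "fit_binomial_glm",
    "GBMConfig",
    "GBMModel",
    "fit_gbm",
    "gbm_importance",
    "predict_expected",
    "evaluate_cv",
]

MUTATION_COLUMNS = ["chrom", "pos0", "ref", "alt", "donor_id"]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic SNV or indel (0-based position, BED-convention)."""

    chrom: str
    pos0: int
    ref: str
    alt: str
    donor_id: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.pos0 < 0:
            raise ValueError("negative position")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def read_mutations(path: str) -> pd.DataFrame:
    """Read the tab-separated mutation dialect chrom/pos0/ref/alt/donor_id.

    A header line is optional and detected by a non-integer second field.
    """
    first = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    has_header = not str(first.iloc[0, 1]).lstrip("-").isdigit()
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=MUTATION_COLUMNS,
        dtype={"chrom": str, "ref": str, "alt": str, "donor_id": str},
    )
    df["pos0"] = df["pos0"].astype(np.int64)
    df["is_indel"] = df["ref"].str.len() != df["alt"].str.len()
    return df


def mutations_from_vcf(path: str, donor_id: str) -> pd.DataFrame:
    """Thin converter from a single-sample VCF to the mutation table.

    VCF positions are 1-based; they are converted to the 0-based convention
    used everywhere else.  Multi-allelic records contribute one row per ALT.
    """
    import pysam  # deferred: VCF ingest is optional

    rows = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                rows.append((rec.chrom, rec.pos - 1, rec.ref, alt, donor_id))
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    df["is_indel"] = df["ref"].str.len() != df["alt"].str.len()
    return df


# ---------------------------------------------------------------------------
# mutation counting
# ---------------------------------------------------------------------------

@dataclass
class MutationCatalog:
    """Per-element observed counts for one cohort.

    ``table`` is indexed by element_id with columns y (mutation count), n_d
    (distinct mutated donors) and L (effective length); ``n_donors`` is the
    cohort size N after hypermutator exclusion, fixed even for donors with
    zero counted mutations.
    """

    table: pd.DataFrame
    n_donors: int
    excluded_donors: tuple[str, ...] = ()

    @property
    def y(self) -> pd.Series:
        return self.table["y"]

    @property
    def n_d(self) -> pd.Series:
        return self.table["n_d"]

    @property
    def L(self) -> pd.Series:
        return self.table["L"]


def _stab_counts(
    starts: np.ndarray,
    ends: np.ndarray,
    owners: np.ndarray,
    pos: np.ndarray,
) -> list[np.ndarray]:
    """For each sorted query position, the interval indices containing it.

    Sweep over intervals sorted by start with an active set pruned by end;
    handles overlapping intervals (elements may overlap across sets).
    """
    order = np.argsort(starts, kind="stable")
    starts, ends, owners = starts[order], ends[order], owners[order]
    hits: list[np.ndarray] = []
    active: list[int] = []
    j = 0
    for p in pos:
        while j < len(starts) and starts[j] <= p:
            active.append(j)
            j += 1
        active = [a for a in active if ends[a] > p]
        hits.append(owners[[a for a in active if starts[a] <= p]])
    return hits


def identify_hypermutators(
    mutations: pd.DataFrame,
    genome_bp: float,
    cutoff_per_mb: float = 30.0,
) -> list[str]:
    """Donors whose genome-wide burden exceeds the cutoff (default 30/Mb)."""
    per_donor = mutations.groupby("donor_id").size()
    rate = per_donor / (genome_bp / 1e6)
    return sorted(rate.index[rate > cutoff_per_mb])


def count_mutations(
    mutations: pd.DataFrame,
    elements: ElementSet,
    mask: RegionMask | None = None,
    donors: list[str] | None = None,
    genome_bp: float | None = None,
    hypermutator_cutoff: float | None = 30.0,
    warn_unknown: bool = True,
) -> MutationCatalog:
    """Count observed mutations and mutated donors per masked element.

    A mutation is counted for *every* element whose masked intervals contain
    its position (half-open, so pos0 == interval end does not count); indels
    are assigned by start position.  ``donors`` fixes the cohort roster (N
    includes donors with zero mutations); when omitted the roster is the set
    of donor_ids observed.  Donors exceeding ``hypermutator_cutoff``
    mutations/Mb (over ``genome_bp``, required for the filter) are removed
    from the roster and their mutations dropped.
    """
    muts = mutations
    excluded: list[str] = []
    if hypermutator_cutoff is not None and genome_bp:
        excluded = identify_hypermutators(muts, genome_bp, hypermutator_cutoff)
        if excluded:
            muts = muts[~muts["donor_id"].isin(excluded)]
    roster = (
        sorted(set(donors) - set(excluded))
        if donors is not None
        else sorted(muts["donor_id"].unique())
    )
    roster_set = set(roster)
    muts = muts[muts["donor_id"].isin(roster_set)]

    if mask is not None:
        elements = _ensure_masked(elements, mask)

    hits = assign_mutations(muts, elements, warn_unknown=warn_unknown)
    eids = [e.element_id for e in elements]
    grouped = hits.groupby("element_id")
    y = grouped.size().reindex(eids, fill_value=0)
    n_d = grouped["donor_id"].nunique().reindex(eids, fill_value=0)
    table = pd.DataFrame(
        {
            "y": y.astype(np.int64),
            "n_d": n_d.astype(np.int64),
            "L": [elements[eid].effective_length for eid in eids],
        },
        index=pd.Index(eids, name="element_id"),
    )
    return MutationCatalog(table, len(roster), tuple(excluded))


def assign_mutations(
    mutations: pd.DataFrame, elements: ElementSet, warn_unknown: bool = True
) -> pd.DataFrame:
    """One row per (mutation, element) containment hit.

    Containment is against the masked intervals (half-open); mutations on
    chromosomes no element touches are skipped with a warning.  A mutation
    inside two overlapping elements yields two rows.
    """
    eids = [e.element_id for e in elements]
    per_chrom: dict[str, list[list]] = {}
    for i, e in enumerate(elements):
        for chrom, ivs in e.masked_intervals.items():
            store = per_chrom.setdefault(chrom, [[], [], []])
            for s, t in ivs:
                store[0].append(s)
                store[1].append(t)
                store[2].append(i)

    unknown = set(mutations["chrom"].unique()) - set(per_chrom)
    if unknown and warn_unknown:
        warnings.warn(
            f"skipping mutations on unknown chromosomes: {sorted(unknown)}"
        )
    frames = []
    for chrom, grp in mutations.groupby("chrom"):
        if chrom not in per_chrom:
            continue
        s, t, o = (np.asarray(a) for a in per_chrom[chrom])
        grp = grp.sort_values("pos0")
        owner_lists = _stab_counts(s, t, o, grp["pos0"].to_numpy())
        counts = np.array([len(ol) for ol in owner_lists])
        if counts.sum() == 0:
            continue
        rep = grp.loc[grp.index.repeat(counts)].reset_index(drop=True)
        rep["element_id"] = [eids[ei] for ol in owner_lists for ei in ol]
        frames.append(rep)
    if not frames:
        return mutations.iloc[0:0].assign(element_id=pd.Series(dtype=str))
    return pd.concat(frames, ignore_index=True)


def _ensure_masked(elements: ElementSet, mask: RegionMask) -> ElementSet:
    from .elements import apply_mask

    return apply_mask(elements, mask)


# ---------------------------------------------------------------------------
# randomised-lasso stability selection
# ---------------------------------------------------------------------------

def _lasso_response(catalog: MutationCatalog) -> np.ndarray:
    """logit((y + 1/2) / (N * L)) — the stabilised per-base rate response."""
    nl = catalog.n_donors * catalog.L.to_numpy(dtype=float)
    return logit((catalog.y.to_numpy(dtype=float) + 0.5) / nl)


@dataclass
class LassoSelection:
    """Result of randomised-lasso feature selection."""

    alpha: float
    importance: pd.Series  # fraction of repeats each feature was selected
    selected: list[str]
    n_repeats: int
    subsample_frac: float

    def __post_init__(self):
        assert ((self.importance >= 0) & (self.importance <= 1)).all()


def select_features_randomized_lasso(
    X: pd.DataFrame,
    catalog: MutationCatalog,
    n_repeats: int = 500,
    subsample_frac: float = 0.10,
    select_cut: float = 0.001,
    keep_threshold: float = 0.5,
    cv_frac: float = 0.33,
    b_range: tuple[float, float] = (0.5, 1.0),
    seed: int = 0,
) -> LassoSelection:
    """Stability selection with per-feature random penalty reweighting.

    The regularisation strength is fixed once by a fivefold CV lasso on a
    ``cv_frac`` subset of the training rows.  Then, ``n_repeats`` times, a
    fresh ``subsample_frac`` subsample is fit with per-feature penalties
    alpha * |w_i| / b_i, b_i ~ U[0.5, 1] (the stability-selection
    "weakness"); a feature counts as selected in a repeat when its
    coefficient magnitude on the original scale reaches ``select_cut``.
    Features selected in more than ``keep_threshold`` of repeats survive.
    X must be the scaled training feature matrix aligned with the catalog.
    """
    if len(X) < 10:
        raise ValueError("need at least 10 training rows for selection")
    if not X.index.equals(catalog.table.index):
        X = X.loc[catalog.table.index]
    Xv = X.to_numpy(dtype=float)
    r = _lasso_response(catalog)
    rng = np.random.default_rng(seed)
    cv_rng = np.random.default_rng(rng.integers(2**31))

    n = len(X)
    cv_idx = cv_rng.choice(n, size=max(int(round(cv_frac * n)), 10), replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = LassoCV(
            alphas=50, cv=5, random_state=int(cv_rng.integers(2**31))
        ).fit(Xv[cv_idx], r[cv_idx])  # 50 log-spaced alphas, min-CV-error rule
    alpha = float(cv.alpha_)

    p = Xv.shape[1]
    hit = np.zeros(p)
    n_sub = max(int(round(subsample_frac * n)), 5)
    for _ in range(n_repeats):
        idx = rng.choice(n, size=n_sub, replace=False)
        b = rng.uniform(*b_range, size=p)
        # penalty alpha*|w_i|/b_i == standard lasso on X*diag(b), w = b*v
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            las = Lasso(alpha=alpha, max_iter=2000).fit(Xv[idx] * b, r[idx])
        w = b * las.coef_
        hit += np.abs(w) >= select_cut
    importance = pd.Series(hit / n_repeats, index=X.columns, name="importance")
    selected = list(importance.index[importance > keep_threshold])
    return LassoSelection(alpha, importance, selected, n_repeats, subsample_frac)


# ---------------------------------------------------------------------------
# binomial GLM
# ---------------------------------------------------------------------------

@dataclass
class GLMModel:
    """Binomial GLM with logit link: yhat/(N*L) = expit(X beta)."""

    beta: pd.Series  # intercept ("const") + selected features
    feature_names: list[str]
    result: object = field(repr=False, default=None)

    def predict_rate(self, X: pd.DataFrame) -> np.ndarray:
        Xm = sm.add_constant(
            X[self.feature_names].to_numpy(dtype=float), has_constant="add"
        )
        return expit(Xm @ self.beta.to_numpy())


def fit_binomial_glm(X_sel: pd.DataFrame, catalog: MutationCatalog) -> GLMModel:
    """Fit y ~ Binomial(n = N*L, p = expit(X beta)) by IRLS.

    Uses the aggregated two-column (successes, failures) response so trials
    up to ~1e10 are handled as rates, never expanded.  Degenerate all-zero
    input fits at the boundary with a warning.
    """
    if not X_sel.index.equals(catalog.table.index):
        X_sel = X_sel.loc[catalog.table.index]
    n = np.round(catalog.n_donors * catalog.L.to_numpy(dtype=float))
    y = catalog.y.to_numpy(dtype=float)
    if (y > n).any():
        raise ValueError("observed count exceeds N*L trials")
    if y.sum() == 0:
        warnings.warn("all-zero response: binomial GLM fit at the boundary")
    Xm = sm.add_constant(X_sel.to_numpy(dtype=float), has_constant="add")
    endog = np.column_stack([y, n - y])
    res = sm.GLM(endog, Xm, family=sm.families.Binomial()).fit()
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(
            f"binomial GLM did not converge: params={res.params}"
        )
    names = ["const"] + list(X_sel.columns)
    return GLMModel(pd.Series(res.params, index=names), list(X_sel.columns), res)


# ---------------------------------------------------------------------------
# gradient-boosted Poisson regression
# ---------------------------------------------------------------------------

@dataclass
class GBMConfig:
    """XGBoost settings for the Poisson BMR model."""

    eta: float = 0.05
    max_depth: int = 8
    subsample: float = 0.6
    max_delta_step: float = 1.2
    early_stop_rounds: int = 5
    nrounds: int = 5000
    val_frac: float = 0.2  # seeded holdout for early stopping


@dataclass
class GBMModel:
    booster: xgb.Booster = field(repr=False)
    feature_names: list[str]
    config: GBMConfig
    best_iteration: int
    log_base_rate: float = 0.0  # intercept: pooled training rate

    def predict_count(self, X: pd.DataFrame, offset: np.ndarray) -> np.ndarray:
        dm = xgb.DMatrix(
            X[self.feature_names].to_numpy(dtype=float),
            base_margin=np.asarray(offset, dtype=float) + self.log_base_rate,
            feature_names=self.feature_names,
        )
        return self.booster.predict(
            dm, iteration_range=(0, self.best_iteration + 1)
        )


def _gbm_params(config: GBMConfig, seed: int) -> dict:
    return {
        "objective": "count:poisson",
        "eta": config.eta,
        "max_depth": config.max_depth,
        "subsample": config.subsample,
        "max_delta_step": config.max_delta_step,
        "eval_metric": "poisson-nloglik",
        "seed": int(seed) % (2**31),
        "nthread": 1,  # bit-reproducibility
        "verbosity": 0,
    }


def fit_gbm(
    X: pd.DataFrame,
    catalog: MutationCatalog,
    config: GBMConfig | None = None,
    seed: int = 0,
) -> GBMModel:
    """Boosted trees for y with Poisson loss and ln(N*L) offset.

    X is the zero-imputed, *unscaled* feature matrix (trees are scale
    invariant).  A seeded ``val_frac`` split provides early stopping.
    """
    config = config or GBMConfig()
    if not X.index.equals(catalog.table.index):
        X = X.loc[catalog.table.index]
    usable = catalog.L.to_numpy(dtype=float) > 0
    if not usable.all():  # untestable elements carry no exposure
        X = X.loc[usable]
        catalog = MutationCatalog(catalog.table.loc[usable], catalog.n_donors)
    y = catalog.y.to_numpy(dtype=float)
    if y.sum() == 0:
        warnings.warn("all-zero response: GBM will predict ~0 everywhere")
    nl = catalog.n_donors * catalog.L.to_numpy(dtype=float)
    # fold the pooled rate into the margin so boosting starts at the
    # intercept-only solution rather than descending ~10 log-units from 1
    log_base_rate = float(np.log(max(y.sum() / nl.sum(), 1e-15)))
    offset = np.log(nl) + log_base_rate
    rng = np.random.default_rng(seed)
    n = len(X)
    n_val = max(int(round(config.val_frac * n)), 1)
    val_idx = rng.choice(n, size=n_val, replace=False)
    is_val = np.zeros(n, dtype=bool)
    is_val[val_idx] = True
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    dtrain = xgb.DMatrix(
        Xv[~is_val], label=y[~is_val], base_margin=offset[~is_val],
        feature_names=names,
    )
    dval = xgb.DMatrix(
        Xv[is_val], label=y[is_val], base_margin=offset[is_val],
        feature_names=names,
    )
    booster = xgb.train(
        _gbm_params(config, seed),
        dtrain,
        num_boost_round=config.nrounds,
        evals=[(dval, "val")],
        early_stopping_rounds=config.early_stop_rounds,
        verbose_eval=False,
    )
    best = getattr(booster, "best_iteration", None)
    if best is None:
        best = booster.num_boosted_rounds() - 1
    return GBMModel(booster, names, config, int(best), log_base_rate)


def gbm_importance(model: GBMModel) -> pd.DataFrame:
    """Per-feature gain importance: `share` sums to 1, `normalized` has max 1.

    Features never used by any tree score 0.
    """
    raw = model.booster.get_score(importance_type="gain")
    gains = pd.Series(
        {f: raw.get(f, 0.0) for f in model.feature_names}, dtype=float
    )
    total = gains.sum()
    share = gains / total if total > 0 else gains
    peak = gains.max()
    normalized = gains / peak if peak > 0 else gains
    return pd.DataFrame({"share": share, "normalized": normalized})


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

_PERSIST_SCHEMA_VERSION = 1


def save_model(model: GLMModel | GBMModel, path: str) -> None:
    """Persist a fitted BMR model with its feature schema (JSON on disk)."""
    import json

    meta = {"schema_version": _PERSIST_SCHEMA_VERSION,
            "feature_names": model.feature_names}
    if isinstance(model, GLMModel):
        meta["kind"] = "glm"
        meta["beta"] = {k: float(v) for k, v in model.beta.items()}
    else:
        meta["kind"] = "gbm"
        meta["config"] = model.config.__dict__
        meta["best_iteration"] = model.best_iteration
        meta["log_base_rate"] = model.log_base_rate
        meta["booster"] = model.booster.save_raw(raw_format="json").decode()
    with open(path, "w") as fh:
        json.dump(meta, fh)


def load_model(path: str) -> GLMModel | GBMModel:
    import json

    with open(path) as fh:
        meta = json.load(fh)
    if meta.get("schema_version") != _PERSIST_SCHEMA_VERSION:
        raise ValueError("unsupported model file version")
    if meta["kind"] == "glm":
        beta = pd.Series(meta["beta"])
        return GLMModel(beta, meta["feature_names"])
    booster = xgb.Booster()
    booster.load_model(bytearray(meta["booster"].encode()))
    return GBMModel(
        booster, meta["feature_names"], GBMConfig(**meta["config"]),
        meta["best_iteration"], meta["log_base_rate"],
    )


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------

def predict_expected(
    model: GLMModel | GBMModel,
    X: pd.DataFrame,
    catalog_or_L,
    n_donors: int | None = None,
) -> pd.Series:
    """Expected mutation counts yhat per element (NaN for untestable ones)."""
    if isinstance(catalog_or_L, MutationCatalog):
        L = catalog_or_L.L
        N = catalog_or_L.n_donors
    else:
        L = pd.Series(catalog_or_L)
        if n_donors is None:
            raise ValueError("n_donors required when passing raw lengths")
        N = n_donors
    L = L.reindex(X.index)
    missing = set(model.feature_names) - set(X.columns)
    if missing:
        raise ValueError(f"feature matrix lacks model features: {sorted(missing)}")
    testable = L.to_numpy(dtype=float) > 0
    nl = N * L.to_numpy(dtype=float)
    yhat = np.full(len(X), np.nan)
    if testable.any():
        Xt = X.loc[testable]
        if isinstance(model, GLMModel):
            yhat[testable] = nl[testable] * model.predict_rate(Xt)
        else:
            yhat[testable] = model.predict_count(Xt, np.log(nl[testable]))
    return pd.Series(yhat, index=X.index, name="yhat")


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss = np.sum((y - y.mean()) ** 2)
    if ss == 0:
        return float("nan")
    return 1.0 - np.sum((y - yhat) ** 2) / ss


def evaluate_cv(
    model_kind: str,
    X: pd.DataFrame,
    catalog: MutationCatalog,
    k_folds: int = 5,
    mode: str = "standard",
    gbm_config: GBMConfig | None = None,
    seed: int = 0,
) -> dict:
    """K-fold predictive evaluation of a BMR model (R^2 and Pearson's r).

    ``standard`` trains on k-1 folds and tests on the held-out fold (used
    for megabase bins); ``inverted`` trains on one fold and tests on the
    remaining k-1 (used for the very large training-element sets).  SEM of
    both metrics is computed across folds; folds with zero variance in y
    contribute missing values.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if mode not in ("standard", "inverted"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = len(X)
    fold = rng.permutation(n) % k_folds
    r2s, rs = [], []
    for f in range(k_folds):
        train = (fold != f) if mode == "standard" else (fold == f)
        test = ~train
        sub = MutationCatalog(catalog.table.iloc[train], catalog.n_donors)
        if model_kind == "glm":
            m = fit_binomial_glm(X.iloc[train], sub)
        elif model_kind == "gbm":
            m = fit_gbm(
                X.iloc[train], sub, gbm_config, seed=int(rng.integers(2**31))
            )
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")
        yhat = predict_expected(
            m, X.iloc[test], catalog.L.iloc[test], catalog.n_donors
        ).to_numpy()
        y = catalog.y.iloc[test].to_numpy(dtype=float)
        ok = np.isfinite(yhat)
        y, yhat = y[ok], yhat[ok]
        if len(y) < 2 or np.var(y) == 0:
            r2s.append(np.nan)
            rs.append(np.nan)
            continue
        r2s.append(_r2(y, yhat))
        rs.append(float(np.corrcoef(y, yhat)[0, 1]))
    r2s, rs = np.array(r2s), np.array(rs)

    def sem(v):
        v = v[np.isfinite(v)]
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

    return {
        "R2": float(np.nanmean(r2s)),
        "pearson_r": float(np.nanmean(rs)),
        "sem_R2": sem(r2s),
        "sem_r": sem(rs),
        "fold_R2": r2s.tolist(),
        "fold_r": rs.tolist(),
    }
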