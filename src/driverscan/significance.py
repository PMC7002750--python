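"""Significance engine: balanced counts, overdispersion-switched null,
functional adjustment and Benjamini-Hochberg correction.

Each element's balanced count y_b = sqrt(y * n_d) (geometric mean of
mutation and mutated-donor counts, damping single-donor hypermutation) is
tested against the model expectation yhat under either a binomial null
B(N*L, yhat/(N*L)) or, when the cohort's training residuals show
significant overdispersion, a negative binomial NB2 null with variance
yhat + s*theta*yhat^2.  Elements nearly significant after cohort-level BH
(q < q_gate) have their counts re-weighted by the functional weight w and
are re-tested; global BH across cohorts defines the final driver calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "balanced_count",
    "DispersionEstimate",
    "overdispersion_test",
    "burden_pvalue",
    "bh_qvalues",
    "AdjustmentConfig",
    "run_significance",
]


def balanced_count(y: float, n_d: float) -> float:
    """Geometric mean sqrt(y * n_d) of mutation count and donor count."""
    if y < 0 or n_d < 0:
        raise ValueError("counts must be non-negative")
    return math.sqrt(y * n_d)


@dataclass
class DispersionEstimate:
    """NB2 dispersion (Var = mu + theta*mu^2) and overdispersion-test p."""

    theta: float
    p_od: float
    s: float = 1.0  # cohort scaling (3 for lymphomas)

    def __post_init__(self):
        if self.theta < 0 or self.s <= 0:
            raise ValueError("theta must be >= 0 and s > 0")

    @property
    def effective_theta(self) -> float:
        return self.s * self.theta


def overdispersion_test(
    y_train: np.ndarray, yhat_train: np.ndarray, s: float = 1.0
) -> DispersionEstimate:
    """Regression-based (Cameron-Trivedi) overdispersion test.

    Regress z_i = ((y_i - yhat_i)^2 - y_i) / yhat_i on yhat_i through the
    origin; the slope estimates the NB2 theta (truncated at 0) and its
    one-sided t test gives p_od.  A heteroskedasticity-robust (HC0)
    standard error is used, since Var(z_i) varies with yhat_i.  Elements
    with yhat = 0 are excluded; fewer than 30 usable elements is an error.
    """
    y = np.asarray(y_train, dtype=float)
    mu = np.asarray(yhat_train, dtype=float)
    ok = np.isfinite(mu) & (mu > 0) & np.isfinite(y)
    y, mu = y[ok], mu[ok]
    n = len(y)
    if n < 30:
        raise ValueError(f"overdispersion test underpowered: {n} < 30 elements")
    z = ((y - mu) ** 2 - y) / mu
    sxx = float(np.sum(mu * mu))
    slope = float(np.sum(z * mu) / sxx)
    resid = z - slope * mu
    # HC0 sandwich variance for the through-origin slope
    var = float(np.sum((mu * resid) ** 2)) / sxx**2
    if var <= 0:
        return DispersionEstimate(max(slope, 0.0), 1.0, s)
    t = slope / math.sqrt(var)
    p_od = float(stats.t.sf(t, df=n - 1))
    return DispersionEstimate(max(slope, 0.0), p_od, s)


def burden_pvalue(
    y_eff: float,
    yhat: float,
    N: float,
    L: float,
    disp: DispersionEstimate | None = None,
    od_cut: float = 0.01,
) -> float:
    """Upper-tail p-value P(Y >= ceil(y_eff)) for one element.

    The null is NB2(mean yhat, dispersion s*theta) when the cohort's
    overdispersion test rejects (p_od <= od_cut, theta > 0), else
    Binomial(n = round(N*L), p = yhat/(N*L)).  Tails are computed through
    scipy's regularised beta/gamma routines, stable for n up to ~1e10.
    """
    if yhat <= 0 or L <= 0:
        raise ValueError("yhat and L must be positive")
    if y_eff <= 0:
        return 1.0
    k = math.ceil(y_eff - 1e-9)
    use_nb = (
        disp is not None
        and disp.p_od <= od_cut
        and disp.effective_theta > 0
    )
    if use_nb:
        th = disp.effective_theta
        r = 1.0 / th
        p = r / (r + yhat)
        return float(stats.nbinom.sf(k - 1, r, p))
    n = round(N * L)
    rate = yhat / (N * L)
    if rate >= 1.0:
        raise ValueError("expected count exceeds N*L under the binomial null")
    return float(stats.binom.sf(k - 1, n, rate))


def bh_qvalues(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass
class AdjustmentConfig:
    """Functional-adjustment and significance thresholds.

    ``F`` is the assumed fraction of functionally relevant variants among
    all observed variants; it fixes the threshold score S_T = -10*log10(F).
    Elements with cohort q < ``q_gate`` are functionally re-weighted;
    global q < ``q_sig`` defines the final driver list.
    """

    F: float = 0.01
    q_gate: float = 0.25
    q_sig: float = 0.1
    od_cut: float = 0.01

    def __post_init__(self):
        if not 0.0 < self.F < 1.0:
            raise ValueError("F must lie in (0, 1)")
        if not 0.0 < self.q_sig < self.q_gate < 1.0:
            raise ValueError("need 0 < q_sig < q_gate < 1")

    @property
    def S_T(self) -> float:
        return -10.0 * math.log10(self.F)


RESULT_COLUMNS = [
    "element_id", "set", "cohort", "y", "n_d", "L", "yhat", "S_combined",
    "w", "y_b", "y_f", "p_raw", "p_func", "q_cohort", "q_global", "flag",
]


def run_significance(
    table: pd.DataFrame,
    dispersion: dict[str, DispersionEstimate] | DispersionEstimate | None,
    cfg: AdjustmentConfig | None = None,
) -> pd.DataFrame:
    """Score a cohort table of elements for driver significance.

    ``table`` needs columns element_id, y, n_d, L, yhat and N (cohort
    size); optional columns cohort, set, w (functional weight, NaN/absent
    meaning neutral 1) and S_combined.  Steps: (1) raw p from the balanced
    count y_b; (2) per-cohort BH; (3) elements with cohort q < q_gate get
    y_f = w * y_b and a recomputed function-adapted p; (4) per-cohort and
    global BH on the function-adapted p.  ``is_significant`` is global
    q < q_sig.  ``dispersion`` is one estimate, or a per-cohort dict, or
    None (binomial null everywhere).
    """
    cfg = cfg or AdjustmentConfig()
    df = table.copy()
    if "cohort" not in df:
        df["cohort"] = "cohort"
    if "set" not in df:
        df["set"] = "all"
    if "w" not in df:
        df["w"] = np.nan
    if "S_combined" not in df:
        df["S_combined"] = np.nan
    required = {"element_id", "y", "n_d", "L", "yhat", "N"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = df.loc[~np.isfinite(df["yhat"]) | (df["yhat"] <= 0), "element_id"]
    if len(bad):
        raise ValueError(
            "elements lack a positive expected count: "
            + ", ".join(map(str, bad.head(10)))
        )

    def disp_for(cohort: str) -> DispersionEstimate | None:
        if dispersion is None or isinstance(dispersion, DispersionEstimate):
            return dispersion
        return dispersion.get(cohort)

    df["flag"] = ""
    df["y_b"] = [balanced_count(y, nd) for y, nd in zip(df["y"], df["n_d"])]
    df["p_raw"] = [
        burden_pvalue(yb, yh, N, L, disp_for(c), cfg.od_cut)
        for yb, yh, N, L, c in zip(
            df["y_b"], df["yhat"], df["N"], df["L"], df["cohort"]
        )
    ]

    # cohort-level BH on the raw p gates the functional adjustment
    df["q_raw_cohort"] = np.nan
    for _, idx in df.groupby("cohort").groups.items():
        df.loc[idx, "q_raw_cohort"] = bh_qvalues(df.loc[idx, "p_raw"])

    w_eff = df["w"].fillna(1.0).to_numpy(dtype=float)
    gated = (df["q_raw_cohort"] < cfg.q_gate).to_numpy()
    df["y_f"] = np.where(gated, w_eff * df["y_b"].to_numpy(), df["y_b"])
    df.loc[gated, "flag"] = "functional-adjusted"
    p_func = df["p_raw"].to_numpy(dtype=float).copy()
    for i in np.flatnonzero(gated):
        row = df.iloc[i]
        p_func[i] = burden_pvalue(
            row["y_f"], row["yhat"], row["N"], row["L"],
            disp_for(row["cohort"]), cfg.od_cut,
        )
    df["p_func"] = p_func

    df["q_cohort"] = np.nan
    for _, idx in df.groupby("cohort").groups.items():
        df.loc[idx, "q_cohort"] = bh_qvalues(df.loc[idx, "p_func"])
    df["q_global"] = bh_qvalues(df["p_func"])
    df["is_significant"] = df["q_global"] < cfg.q_sig
    ordered = RESULT_COLUMNS + ["q_raw_cohort", "N", "is_significant"]
    return df[[c for c in ordered if c in df.columns]]
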