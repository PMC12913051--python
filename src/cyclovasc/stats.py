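"""Endocrine inference layer: hormone mixed models, state PCA, power.

The design has each participant measured in up to three menstrual phases
(EFP, LFP, MLP) with serum oestradiol (pmol/L) and progesterone (nmol/L)
drawn at every session.  Because the two hormones are correlated across
sessions, progesterone is residualised on oestradiol by ordinary least
squares ("resProgesterone"); the residuals carry progesterone variance
independent of oestradiol.

Each vascular outcome is modelled with a linear mixed model: oestradiol
and resProgesterone as fixed-effect slopes, ROI (reference level =
"global") and laterality added when the outcome has them, and a
participant random intercept.  Each hormone's contribution is tested by
a likelihood-ratio test (chi-square, df = 1) between maximum-likelihood
fits with and without that hormone's slope; slopes and standard errors
are reported from the REML fit of the full model, with confidence
intervals using t critical values at residual degrees of freedom.

A significant main effect gates an ROI x hormone interaction follow-up;
per-ROI Wald contrasts compare each ROI's hormone slope against the
global-average reference level.  High/low endocrine-state comparison
selects per-participant extreme phases (ties resolved towards EFP for
the low state and MLP for the high state), z-scores the outcome matrix,
performs PCA on its Pearson correlation matrix, and projects the high
state onto the low state's components; alignment is measured with
per-observation cos2 on the first two components.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sp_stats

__all__ = [
    "PHASES",
    "LmmResult",
    "StateComparison",
    "residualize_progesterone",
    "fit_hormone_lmm",
    "exclude_outlier_residuals",
    "test_interaction",
    "select_extreme_phases",
    "state_pca",
    "project_condition",
    "power_one_sample_t",
    "required_sample_size",
    "monte_carlo_power",
    "across_cycle_change",
]

logger = logging.getLogger(__name__)

PHASES = ("EFP", "LFP", "MLP")
HORMONES = ("oestradiol", "res_progesterone")


# ---------------------------------------------------------------------------
# hormone panel


def residualize_progesterone(panel: pd.DataFrame) -> pd.DataFrame:
    """Add ``res_progesterone``: progesterone residualised on oestradiol.

    OLS of progesterone on oestradiol (with intercept) pooled over all
    sessions; the residuals have exactly zero sample covariance with
    oestradiol.  With constant oestradiol the regression is degenerate
    and the residuals reduce to mean-centred progesterone (warned).
    """
    panel = panel.copy()
    sub = panel.dropna(subset=["oestradiol", "progesterone"])
    if len(sub) < 3:
        raise ValueError("need at least 3 complete hormone observations")
    e2 = sub["oestradiol"].to_numpy(float)
    p4 = sub["progesterone"].to_numpy(float)
    if np.ptp(e2) == 0:
        warnings.warn("oestradiol is constant; residuals are mean-centred "
                      "progesterone", stacklevel=2)
        fitted = np.full_like(p4, p4.mean())
    else:
        design = np.column_stack([np.ones_like(e2), e2])
        beta, *_ = np.linalg.lstsq(design, p4, rcond=None)
        fitted = design @ beta
    panel.loc[sub.index, "res_progesterone"] = p4 - fitted
    return panel


# ---------------------------------------------------------------------------
# linear mixed models


@dataclass
class LmmResult:
    """Per-hormone mixed-model inference for one outcome."""

    metric: str
    hormone: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    chi2: float
    df: int
    p: float
    n_obs: int
    excluded_outliers: int = 0
    converged: bool = True


def _fit_mixed(formula: str, data: pd.DataFrame, reml: bool):
    """MixedLM fit with optimizer fallback; raises if every method fails."""
    model = smf.mixedlm(formula, data, groups=data["participant"])
    last_exc: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=reml, method=method, maxiter=1000)
            if np.isfinite(res.llf):
                return res
        except Exception as exc:  # singular Hessian, non-convergence, ...
            last_exc = exc
    raise RuntimeError(f"mixed-model fit failed for {formula!r}: {last_exc}")


def _prepare(table: pd.DataFrame, metric: str) -> tuple[pd.DataFrame, list[str]]:
    """Subset one metric, scale hormones to unit SD, build extra terms."""
    df = table[table["metric"] == metric].copy() if "metric" in table else table.copy()
    df = df.dropna(subset=["value", *HORMONES])
    if df.empty:
        raise ValueError(f"no usable rows for metric {metric!r}")
    key_cols = [c for c in ("participant", "phase", "roi", "laterality")
                if c in df]
    if df.duplicated(subset=key_cols).any():
        raise ValueError("duplicated (participant, phase, roi, laterality) rows")
    extra: list[str] = []
    if "roi" in df and df["roi"].nunique() > 1:
        df["roi"] = pd.Categorical(
            df["roi"],
            categories=(["global"] + sorted(set(df["roi"]) - {"global"})
                        if "global" in set(df["roi"]) else sorted(set(df["roi"]))))
        extra.append("C(roi)")
    if "laterality" in df and df["laterality"].nunique() > 1:
        extra.append("C(laterality)")
    for h in HORMONES:
        df[f"_{h}_scale"] = df[h].std(ddof=1)
        df[f"_{h}_z"] = df[h] / df[f"_{h}_scale"]
    return df, extra


def fit_hormone_lmm(table: pd.DataFrame, metric: str,
                    hormones: tuple[str, ...] = HORMONES,
                    excluded_outliers: int = 0) -> dict[str, LmmResult]:
    """Random-intercept mixed model of one outcome with per-hormone LRTs.

    ``table`` is a long-format frame with columns ``participant``,
    ``phase``, ``value``, the hormone columns, and optionally ``metric``
    (for filtering), ``roi`` and ``laterality``.  Hormone predictors are
    standardised internally for optimizer stability; slopes and standard
    errors are rescaled back to outcome units per hormone unit.
    """
    df, extra = _prepare(table, metric)
    if df["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    zs = [f"_{h}_z" for h in hormones]
    rhs_full = " + ".join(zs + extra)
    full_ml = _fit_mixed(f"value ~ {rhs_full}", df, reml=False)
    full_reml = _fit_mixed(f"value ~ {rhs_full}", df, reml=True)
    n_obs = int(full_ml.nobs)
    resid_df = max(n_obs - len(full_ml.fe_params) - 1, 1)
    tcrit = sp_stats.t.ppf(0.975, resid_df)

    out: dict[str, LmmResult] = {}
    for h in hormones:
        others = [f"_{o}_z" for o in hormones if o != h]
        rhs_red = " + ".join(others + extra) if (others or extra) else "1"
        red_ml = _fit_mixed(f"value ~ {rhs_red}", df, reml=False)
        chi2 = max(2.0 * (full_ml.llf - red_ml.llf), 0.0)
        if not np.isfinite(chi2):
            warnings.warn(f"degenerate LRT for {h} (infinite likelihood "
                          "ratio); p reported as 0", stacklevel=2)
            chi2, p = np.inf, 0.0
        else:
            p = float(sp_stats.chi2.sf(chi2, 1))
        scale = float(df[f"_{h}_scale"].iloc[0])
        slope = float(full_reml.params[f"_{h}_z"]) / scale
        se = float(full_reml.bse[f"_{h}_z"]) / scale
        out[h] = LmmResult(metric=metric, hormone=h, slope=slope, se=se,
                           ci_low=slope - tcrit * se,
                           ci_high=slope + tcrit * se,
                           chi2=float(chi2), df=1, p=p, n_obs=n_obs,
                           excluded_outliers=excluded_outliers,
                           converged=bool(full_ml.converged))
    return out


def exclude_outlier_residuals(table: pd.DataFrame, metric: str, k: float = 2.5,
                              hormones: tuple[str, ...] = HORMONES
                              ) -> tuple[pd.DataFrame, dict[str, LmmResult]]:
    """Drop rows with |standardised model residual| > k and refit once.

    Returns the filtered table (all metrics retained; only rows of the
    target metric can be dropped) and the refitted results, which carry
    the exclusion count.
    """
    df, extra = _prepare(table, metric)
    zs = [f"_{h}_z" for h in hormones]
    rhs = " + ".join(zs + extra)
    fit = _fit_mixed(f"value ~ {rhs}", df, reml=False)
    resid = np.asarray(fit.resid)
    sd = resid.std(ddof=1)
    keep = (np.abs(resid - resid.mean()) <= k * sd) if sd > 0 else np.ones(
        len(resid), bool)
    n_excluded = int((~keep).sum())
    kept_idx = df.index[keep]
    dropped_idx = df.index[~keep]
    if n_excluded:
        gone = set(df["participant"]) - set(df.loc[kept_idx, "participant"])
        if gone:
            warnings.warn(f"outlier exclusion removed all rows of "
                          f"participants {sorted(gone)}", stacklevel=2)
    if "metric" in table:
        filtered = table.drop(index=dropped_idx)
    else:
        filtered = table.loc[kept_idx]
    results = fit_hormone_lmm(filtered, metric, hormones,
                              excluded_outliers=n_excluded)
    return filtered, results


def test_interaction(table: pd.DataFrame, metric: str, hormone: str,
                     main_effect_p: float | None = None) -> dict:
    """ROI x hormone interaction follow-up of a significant main effect.

    Refuses to run unless the hormone's main effect is significant at
    p < 0.05 (computed here if ``main_effect_p`` is not given).  Returns
    the interaction LRT (df = number of extra slopes) and per-ROI Wald
    t-contrasts of the ROI-specific hormone slope against the
    global-average reference level.
    """
    df, extra = _prepare(table, metric)
    if "C(roi)" not in extra:
        raise ValueError("interaction requires a metric with multiple ROIs")
    if main_effect_p is None:
        main_effect_p = fit_hormone_lmm(table, metric)[hormone].p
    if not main_effect_p < 0.05:
        raise ValueError(
            f"interaction follow-up is gated on a significant main effect "
            f"(p = {main_effect_p:.3g} >= 0.05)")
    zcol = f"_{hormone}_z"
    scale = float(df[f"{zcol[:-2]}_scale"].iloc[0])
    zs = [f"_{h}_z" for h in HORMONES]
    rhs_main = " + ".join(zs + extra)
    main = _fit_mixed(f"value ~ {rhs_main}", df, reml=False)
    rhs_int = rhs_main + f" + C(roi):{zcol}"
    inter = _fit_mixed(f"value ~ {rhs_int}", df, reml=False)
    chi2 = max(2.0 * (inter.llf - main.llf), 0.0)
    df_int = len(inter.fe_params) - len(main.fe_params)
    p = float(sp_stats.chi2.sf(chi2, df_int))

    resid_df = max(int(inter.nobs) - len(inter.fe_params) - 1, 1)
    contrasts = {}
    for name in inter.fe_params.index:
        if not name.startswith("C(roi)[T.") or not name.endswith(f"]:{zcol}"):
            continue
        roi = name[len("C(roi)[T."):-len(f"]:{zcol}")]
        est = float(inter.params[name]) / scale
        se = float(inter.bse[name]) / scale
        t = est / se
        contrasts[roi] = {
            "estimate": est, "se": se, "t": t, "df": resid_df,
            "p": float(2.0 * sp_stats.t.sf(abs(t), resid_df)),
        }
    return {"chi2": float(chi2), "df": df_int, "p": p,
            "roi_contrasts": contrasts}


# ---------------------------------------------------------------------------
# endocrine-state selection and PCA


def select_extreme_phases(panel: pd.DataFrame, hormone: str) -> pd.DataFrame:
    """Per-participant lowest and highest hormone phase.

    Ties go to the earlier phase (EFP > LFP > MLP priority) for the low
    condition and the later phase (MLP > LFP > EFP) for the high
    condition.  Participants with a single recorded phase are excluded
    (logged).
    """
    order = {p: i for i, p in enumerate(PHASES)}
    rows = []
    for pid, grp in panel.dropna(subset=[hormone]).groupby("participant"):
        grp = grp.sort_values("phase", key=lambda s: s.map(order))
        if len(grp) < 2:
            logger.info("participant %s has a single phase; excluded", pid)
            continue
        vals = grp[hormone].to_numpy(float)
        low_i = int(np.argmin(vals))                  # earliest minimum
        high_i = int(len(vals) - 1 - np.argmax(vals[::-1]))  # latest maximum
        rows.append({"participant": pid,
                     "low_phase": grp["phase"].iloc[low_i],
                     "high_phase": grp["phase"].iloc[high_i],
                     "low_value": vals[low_i],
                     "high_value": vals[high_i]})
    return pd.DataFrame(rows)


@dataclass
class StateComparison:
    """Correlation-matrix PCA of one endocrine condition."""

    condition: str
    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    correlation: np.ndarray
    eigenvalues: np.ndarray           # descending
    components: np.ndarray            # columns = unit eigenvectors
    explained: np.ndarray             # fractions, sum to 1
    loadings: np.ndarray              # eigvec * sqrt(eigval)
    scores: np.ndarray                # observations x components
    obs_cos2: np.ndarray              # observations x components
    var_cos2: np.ndarray              # variables x components


def _zscore(data: pd.DataFrame, means=None, sds=None):
    x = data.to_numpy(float)
    if means is None:
        means = np.nanmean(x, axis=0)
        sds = np.nanstd(x, axis=0, ddof=1)
    z = (x - means) / sds
    z = np.where(np.isnan(z), 0.0, z)  # mean imputation after z-scoring
    return z, means, sds


def state_pca(data: pd.DataFrame, condition: str = "") -> StateComparison:
    """PCA of the Pearson correlation matrix of standardised outcomes.

    ``data`` is observations (participants) x variables.  All-missing
    variables are dropped with a warning; remaining missing cells are
    mean-imputed after z-scoring (flagged in the log).
    """
    all_missing = [c for c in data.columns if data[c].isna().all()]
    if all_missing:
        warnings.warn(f"dropping all-missing variables: {all_missing}",
                      stacklevel=2)
        data = data.drop(columns=all_missing)
    n_imputed = int(data.isna().to_numpy().sum())
    if n_imputed:
        logger.info("mean-imputing %d missing cells after z-scoring",
                    n_imputed)
    z, means, sds = _zscore(data)
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    idx = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[idx], 0.0, None)
    eigvec = eigvec[:, idx]
    # deterministic sign: largest-|loading| element positive
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    explained = eigval / eigval.sum()
    loadings = eigvec * np.sqrt(eigval)
    scores = z @ eigvec
    row_norm2 = (scores ** 2).sum(axis=1, keepdims=True)
    obs_cos2 = np.divide(scores ** 2, row_norm2,
                         out=np.zeros_like(scores), where=row_norm2 > 0)
    var_cos2 = loadings ** 2
    return StateComparison(condition=condition, variables=list(data.columns),
                           means=means, sds=sds, correlation=corr,
                           eigenvalues=eigval, components=eigvec,
                           explained=explained, loadings=loadings,
                           scores=scores, obs_cos2=obs_cos2,
                           var_cos2=var_cos2)


def project_condition(high_data: pd.DataFrame, low: StateComparison,
                      n_components: int = 2) -> dict:
    """Project high-state data onto the low state's component space.

    High-state observations are standardised with the low condition's
    means/SDs, scored on the low-condition eigenvectors, and compared by
    mean per-observation cos2 on the leading components:
    ``percent change = (mean cos2 high - mean cos2 low)/mean cos2 low * 100``.
    """
    if list(high_data.columns) != low.variables:
        missing = set(low.variables) ^ set(high_data.columns)
        raise ValueError(f"variable sets differ between conditions: "
                         f"{sorted(missing)}")
    z, _, _ = _zscore(high_data, low.means, low.sds)
    scores = z @ low.components
    row_norm2 = (scores ** 2).sum(axis=1, keepdims=True)
    cos2 = np.divide(scores ** 2, row_norm2,
                     out=np.zeros_like(scores), where=row_norm2 > 0)
    change = {}
    for comp in range(n_components):
        lo = float(low.obs_cos2[:, comp].mean())
        hi = float(cos2[:, comp].mean())
        change[comp + 1] = (hi - lo) / lo * 100.0 if lo > 0 else np.nan
    return {"scores": scores, "obs_cos2": cos2,
            "alignment_change_pct": change}


# ---------------------------------------------------------------------------
# power


def power_one_sample_t(n: int, dz: float, alpha: float = 0.05) -> float:
    """Exact power of a two-sided one-sample (paired-difference) t-test."""
    if n < 2:
        return 0.0
    df = n - 1
    tcrit = sp_stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = dz * np.sqrt(n)
    return float(sp_stats.nct.sf(tcrit, df, nc)
                 + sp_stats.nct.cdf(-tcrit, df, nc))


def required_sample_size(dz: float, power: float = 0.90,
                         alpha: float = 0.05, n_max: int = 100_000) -> int:
    """Smallest n whose exact noncentral-t power reaches ``power``."""
    if dz <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if power_one_sample_t(n, dz, alpha) >= power:
            return n
    raise ValueError(f"power {power} unreachable within n <= {n_max}")


def monte_carlo_power(n: int, dz: float, alpha: float = 0.05,
                      n_sims: int = 100_000, seed: int = 0) -> float:
    """Simulation estimate of one-sample t-test power (oracle cross-check)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sims, n)) + dz
    t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
    tcrit = sp_stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    return float(np.mean(np.abs(t) > tcrit))


def across_cycle_change(slope: float, hormone_range: float) -> float:
    """Across-cycle outcome change implied by a fixed-effect slope.

    The product of a hormone slope (outcome units per hormone unit) and
    the average within-participant max-min hormone excursion.
    """
    return slope * hormone_range
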