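"""Attribution battery for terracing SOC analysis.

Climate stratification, univariate screens, varimax-rotated PCA, linear
mixed-effects models with marginal/conditional R², three-group variation
partitioning, VIF pruning and random-forest Monte Carlo cross-validation.

Stratification convention: the binary humid/arid split is at aridity index
(AI = MAP/PET) 1.0, the hydrological transition between water-deficit and
water-surplus conditions; climate zones are semi-arid [0.2, 0.5),
semi-humid [0.5, 0.65) and humid [0.65, inf).  AI exactly 1.0 classifies
as humid (documented tie-break).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import ShuffleSplit
from statsmodels.multivariate.factor_rotation import rotate_factors
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Climate stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClimateClass:
    binary: str  # "arid" | "humid"
    zone: str  # "semi-arid" | "semi-humid" | "humid" | "extreme-arid"
    extreme_arid: bool = False


def classify_climate(ai: float) -> ClimateClass:
    """Binary (AI threshold 1.0) and ternary climate class from aridity.

    AI below 0.2 is flagged extreme-arid (out of the analysis scope, where
    agricultural terracing is essentially absent).
    """
    if ai <= 0:
        raise ValueError("aridity index must be > 0")
    binary = "humid" if ai >= 1.0 else "arid"
    if ai < 0.2:
        return ClimateClass(binary=binary, zone="extreme-arid", extreme_arid=True)
    if ai < 0.5:
        zone = "semi-arid"
    elif ai < 0.65:
        zone = "semi-humid"
    else:
        zone = "humid"
    return ClimateClass(binary=binary, zone=zone)


# ---------------------------------------------------------------------------
# Univariate screens
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    """Per-cell significance stars: * 0.05, ** 0.01, *** 0.001, blank above."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def screen_univariate(samples: pd.DataFrame, group_col: str,
                      variables: list[str],
                      targets: tuple[str, ...] = ("spr",)) -> pd.DataFrame:
    """Normality check, optional log transform, Welch t-test and Pearson r.

    For each variable: Shapiro-Wilk normality p, whether a log transform
    was applied (skewed and strictly positive data), Welch's t statistic and
    p between the two groups in ``group_col``, and Pearson correlations
    against each target with significance stars (blank for p > 0.05).
    """
    groups = sorted(samples[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    for g in groups:
        if (samples[group_col] == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")

    rows = []
    for var in variables:
        vals = samples[var].to_numpy(float)
        ok = np.isfinite(vals)
        v = vals[ok]
        if len(v) < 3 or np.ptp(v) == 0:
            rows.append({"variable": var, "shapiro_p": np.nan, "log_transformed": False,
                         "t_stat": np.nan, "t_p": np.nan,
                         **{f"r_{t}": np.nan for t in targets},
                         **{f"stars_{t}": "" for t in targets}})
            continue
        shapiro_p = float(sps.shapiro(v[:4999]).pvalue)
        transformed = shapiro_p < 0.05 and np.all(v > 0)
        work = np.log10(vals) if transformed else vals

        g1 = work[ok & (samples[group_col] == groups[0]).to_numpy()]
        g2 = work[ok & (samples[group_col] == groups[1]).to_numpy()]
        if np.ptp(work[ok]) == 0 or (np.ptp(g1) == 0 and np.ptp(g2) == 0 and g1.mean() == g2.mean()):
            t_stat, t_p = 0.0, 1.0
        else:
            t = sps.ttest_ind(g1, g2, equal_var=False)
            t_stat, t_p = float(t.statistic), float(t.pvalue)

        row = {"variable": var, "shapiro_p": shapiro_p,
               "log_transformed": bool(transformed),
               "t_stat": t_stat, "t_p": t_p}
        for tgt in targets:
            tv = samples[tgt].to_numpy(float)
            both = ok & np.isfinite(tv)
            if both.sum() < 3 or np.ptp(work[both]) == 0 or np.ptp(tv[both]) == 0:
                row[f"r_{tgt}"], row[f"stars_{tgt}"] = np.nan, ""
            else:
                r, p = sps.pearsonr(work[both], tv[both])
                row[f"r_{tgt}"] = float(r)
                row[f"stars_{tgt}"] = significance_stars(float(p))
        rows.append(row)
    return pd.DataFrame(rows)


def partial_correlation(x: np.ndarray, y: np.ndarray,
                        controls: np.ndarray | pd.DataFrame | None = None) -> float:
    """Correlation of x and y after removing linear effects of the controls.

    Both x and y are regressed on the controls (with intercept); the
    Pearson correlation of the residuals is returned.  With no controls
    this is the zero-order Pearson r.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if controls is None or (hasattr(controls, "shape") and np.size(controls) == 0):
        return float(sps.pearsonr(x, y).statistic)
    C = np.asarray(controls, float)
    if C.ndim == 1:
        C = C[:, None]
    n, k = C.shape
    if n <= k + 2:
        raise ValueError("need n > dim(controls) + 2 observations")
    Z = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError("collinear controls")
    beta_x, _, _, _ = np.linalg.lstsq(Z, x, rcond=None)
    beta_y, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    return float(sps.pearsonr(x - Z @ beta_x, y - Z @ beta_y).statistic)


# ---------------------------------------------------------------------------
# Varimax-rotated PCA
# ---------------------------------------------------------------------------

@dataclass
class RotatedComponents:
    """Varimax-rotated principal components of a standardized covariate panel."""

    loadings: pd.DataFrame  # variables x retained components
    eigenvalues: np.ndarray  # all eigenvalues, descending
    variance_fractions: np.ndarray  # per retained rotated component
    scores: pd.DataFrame  # samples x retained components
    rotation: np.ndarray  # orthonormal rotation matrix
    retention_rule: str = "eigenvalue > 1 and variance fraction > 5%"
    interpretation_threshold: float = 0.5


def rotated_pca(X: pd.DataFrame, min_var_frac: float = 0.05) -> RotatedComponents:
    """Correlation-matrix PCA with varimax rotation of the retained set.

    Components are retained when their eigenvalue exceeds 1 and they
    explain more than ``min_var_frac`` of total variance; loadings with
    absolute value above 0.5 are the conventional interpretation threshold.
    """
    X = pd.DataFrame(X)
    if len(X) < 2:
        raise ValueError("rotated PCA needs at least 2 samples")
    sd = X.std(ddof=1)
    keep = sd[sd > 0].index.tolist()
    if len(keep) < 2:
        raise ValueError("need >= 2 variables with nonzero variance")
    Xs = (X[keep] - X[keep].mean()) / X[keep].std(ddof=1)
    corr = np.corrcoef(Xs.to_numpy(float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    p = len(keep)

    retained = np.flatnonzero((eigval > 1.0) & (eigval / p > min_var_frac))
    if retained.size == 0:
        retained = np.array([0])  # keep the leading component as a fallback
        logger.warning("no component passed retention; keeping the first")
    k = int(retained.max()) + 1

    loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
    with np.errstate(invalid="ignore"):
        scores = Xs.to_numpy(float) @ eigvec[:, :k] / np.sqrt(eigval[:k])
    if k >= 2:
        rot_loadings, T = rotate_factors(loadings, "varimax")
    else:
        rot_loadings, T = loadings, np.eye(1)
    # fix signs so each component's dominant loading is positive
    signs = np.sign(rot_loadings[np.argmax(np.abs(rot_loadings), axis=0),
                                 np.arange(k)])
    signs[signs == 0] = 1.0
    rot_loadings = rot_loadings * signs
    rot_scores = (scores @ T) * signs

    names = [f"RC{i + 1}" for i in range(k)]
    var_frac = (rot_loadings**2).sum(axis=0) / p
    return RotatedComponents(
        loadings=pd.DataFrame(rot_loadings, index=keep, columns=names),
        eigenvalues=eigval,
        variance_fractions=var_frac,
        scores=pd.DataFrame(rot_scores, index=X.index, columns=names),
        rotation=T * signs,
    )


# ---------------------------------------------------------------------------
# Linear mixed-effects models
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    """Selected mixed model: standardized fixed effects and R² decomposition."""

    fixed_effects: dict[str, float]  # standardized coefficients
    selected: list[str]
    random_intercept_var: float
    residual_var: float
    r2m: float
    r2c: float
    aic: float
    fallback_fixed_site: bool = False


def _fit_mixed(data: pd.DataFrame, response: str, terms: list[str],
               group_col: str):
    formula = f"{response} ~ " + (" + ".join(terms) if terms else "1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[group_col])
        return model.fit(reml=False, maxiter=200)


def fit_lmm(data: pd.DataFrame, response: str, candidates: list[str],
            group_col: str = "site_id") -> LMMResult:
    """Stepwise (bidirectional, AIC) mixed model with a random site intercept.

    Response and candidate predictors are standardized internally, so the
    reported fixed-effect coefficients are directly comparable relative
    importances.  Marginal R² (fixed effects only) and conditional R²
    (fixed + random) follow the variance-decomposition definition.
    """
    if data[group_col].nunique() < 3:
        raise ValueError("need >= 3 groups for a random intercept")
    work = data[[group_col]].copy()
    cols = [response] + list(candidates)
    for c in cols:
        v = data[c].to_numpy(float)
        s = np.std(v, ddof=1)
        work[c] = (v - v.mean()) / s if s > 0 else 0.0

    def aic_of(terms: list[str]) -> float:
        try:
            return float(_fit_mixed(work, response, terms, group_col).aic)
        except (np.linalg.LinAlgError, ValueError):
            return np.inf

    selected: list[str] = []
    current_aic = aic_of(selected)
    improved = True
    while improved:
        improved = False
        moves = [("add", t) for t in candidates if t not in selected]
        moves += [("drop", t) for t in selected]
        best = (current_aic, None)
        for action, term in moves:
            trial = selected + [term] if action == "add" else [t for t in selected if t != term]
            a = aic_of(trial)
            if a < best[0] - 1e-9:
                best = (a, (action, term))
        if best[1] is not None:
            action, term = best[1]
            if action == "add":
                selected.append(term)
            else:
                selected.remove(term)
            current_aic = best[0]
            improved = True

    fallback = False
    try:
        res = _fit_mixed(work, response, selected, group_col)
        fe = {t: float(res.params[t]) for t in selected}
        var_re = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
        var_resid = float(res.scale)
        X = work[selected].to_numpy(float) if selected else np.zeros((len(work), 0))
        var_fixed = float(np.var(X @ np.array([fe[t] for t in selected]))) if selected else 0.0
        aic = float(res.aic)
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("singular mixed fit; falling back to fixed site effects")
        fallback = True
        formula = f"{response} ~ C({group_col})" + ("".join(f" + {t}" for t in selected))
        ols = smf.ols(formula, work).fit()
        fe = {t: float(ols.params[t]) for t in selected}
        site_means = work.groupby(group_col)[response].transform("mean")
        var_re = float(np.var(site_means))
        var_resid = float(ols.mse_resid)
        X = work[selected].to_numpy(float) if selected else np.zeros((len(work), 0))
        var_fixed = float(np.var(X @ np.array([fe[t] for t in selected]))) if selected else 0.0
        aic = float(ols.aic)

    denom = var_fixed + var_re + var_resid
    r2m = var_fixed / denom if denom > 0 else 0.0
    r2c = (var_fixed + var_re) / denom if denom > 0 else 0.0
    r2m, r2c = float(np.clip(r2m, 0, 1)), float(np.clip(r2c, 0, 1))
    r2c = max(r2c, r2m)
    return LMMResult(fixed_effects=fe, selected=selected,
                     random_intercept_var=var_re, residual_var=var_resid,
                     r2m=r2m, r2c=r2c, aic=aic, fallback_fixed_site=fallback)


# ---------------------------------------------------------------------------
# Variation partitioning
# ---------------------------------------------------------------------------

@dataclass
class VPAResult:
    """Three-group variation partitioning by nested adjusted R²."""

    fractions: dict[str, float]  # raw (may be negative, adjusted R²)
    clipped: dict[str, float]  # non-negative report view
    block_pc_variance: dict[str, float]  # first-PC explained variance per block
    adjusted_r2: dict[str, float]  # the 7 nested regressions


def _first_pc(block: pd.DataFrame, name: str) -> tuple[np.ndarray, float]:
    X = block.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(block.columns, sd) if s == 0]
        raise ValueError(f"block {name!r}: zero-variance variable(s) {bad}")
    Xs = (X - X.mean(axis=0)) / sd
    if Xs.shape[1] == 1:
        return Xs[:, 0], 1.0
    corr = np.corrcoef(Xs, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    i = int(np.argmax(eigval))
    vec = eigvec[:, i]
    if vec.sum() < 0:
        vec = -vec
    score = Xs @ vec
    if np.std(score) == 0:
        raise ValueError(f"block {name!r}: degenerate first principal component")
    return score, float(eigval[i] / Xs.shape[1])


def adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Ezekiel-adjusted R² of an OLS fit with intercept."""
    n = len(y)
    k = X.shape[1]
    Z = np.column_stack([np.ones(n), X])
    beta, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def variation_partition(y: np.ndarray, blocks: dict[str, pd.DataFrame]) -> VPAResult:
    """Partition explained variance in ``y`` among three predictor blocks.

    Each block is reduced to its first principal component (its explained
    variance fraction is reported); the unique, pairwise-shared and triple
    fractions come from the seven nested adjusted-R² regressions via
    inclusion-exclusion, and the residual completes the total to 1.  Raw
    fractions can be slightly negative (a known property of adjusted R²)
    and are reported raw alongside a clipped view.
    """
    if len(blocks) != 3:
        raise ValueError("variation partitioning expects exactly 3 blocks")
    names = list(blocks)
    for a in range(3):
        for b in range(a + 1, 3):
            common = set(blocks[names[a]].columns) & set(blocks[names[b]].columns)
            if common:
                raise ValueError(f"blocks {names[a]!r} and {names[b]!r} share {sorted(common)}")
    y = np.asarray(y, float)

    pcs, pc_var = {}, {}
    for name, block in blocks.items():
        if block.shape[1] == 0:
            raise ValueError(f"block {name!r} is empty")
        pcs[name], pc_var[name] = _first_pc(block, name)

    g1, g2, g3 = (pcs[n][:, None] for n in names)
    r2a = {
        "1": adjusted_r2(y, g1), "2": adjusted_r2(y, g2), "3": adjusted_r2(y, g3),
        "12": adjusted_r2(y, np.hstack([g1, g2])),
        "13": adjusted_r2(y, np.hstack([g1, g3])),
        "23": adjusted_r2(y, np.hstack([g2, g3])),
        "123": adjusted_r2(y, np.hstack([g1, g2, g3])),
    }
    A, B, C = r2a["1"], r2a["2"], r2a["3"]
    AB, AC, BC, ABC = r2a["12"], r2a["13"], r2a["23"], r2a["123"]
    g = A + B + C - AB - AC - BC + ABC
    fr = {
        f"unique_{names[0]}": ABC - BC,
        f"unique_{names[1]}": ABC - AC,
        f"unique_{names[2]}": ABC - AB,
        f"shared_{names[0]}_{names[1]}": A + B - AB - g,
        f"shared_{names[0]}_{names[2]}": A + C - AC - g,
        f"shared_{names[1]}_{names[2]}": B + C - BC - g,
        "shared_all": g,
        "residual": 1.0 - ABC,
    }
    clipped = {k: max(v, 0.0) for k, v in fr.items()}
    return VPAResult(fractions=fr, clipped=clipped, block_pc_variance=pc_var,
                     adjusted_r2=r2a)


# ---------------------------------------------------------------------------
# VIF pruning and random-forest Monte Carlo cross-validation
# ---------------------------------------------------------------------------

def _vif(X: np.ndarray) -> np.ndarray:
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        others = np.delete(X, j, axis=1)
        Z = np.column_stack([np.ones(n), others])
        beta, _, _, _ = np.linalg.lstsq(Z, X[:, j], rcond=None)
        resid = X[:, j] - Z @ beta
        ss_tot = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_prune(X: pd.DataFrame, threshold: float = 5.0) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Iteratively drop the variable with the largest variance inflation
    factor until all VIFs are below ``threshold``.

    Ties break deterministically by column order.  Returns the reduced
    panel and the removal log (variable, VIF at removal).
    """
    if X.shape[1] < 2:
        raise ValueError("VIF pruning needs >= 2 variables")
    work = X.copy()
    removed: list[tuple[str, float]] = []
    while work.shape[1] >= 2:
        vifs = _vif(work.to_numpy(float))
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        name = work.columns[worst]
        removed.append((str(name), float(vifs[worst])))
        work = work.drop(columns=[name])
    return work, removed


@dataclass
class RfCvResult:
    """Random-forest Monte Carlo cross-validation performance."""

    rmse: np.ndarray  # per repetition, validation
    r2: np.ndarray  # per repetition, validation
    importance: pd.DataFrame  # variables x (mean, sd) permutation importance
    importance_per_rep: np.ndarray  # n_rep x p
    variables: list[str]


def rf_mccv(y: np.ndarray, X: pd.DataFrame, n_rep: int = 100,
            test_frac: float = 0.2, seed: int = 0,
            n_trees: int = 500, max_features: str | float = "sqrt",
            n_perm_repeats: int = 3) -> RfCvResult:
    """Random forest with repeated random 4:1 train/validation splits.

    Each repetition refits the forest on a fresh 80/20 split and records
    validation RMSE, R² and permutation variable importance; importances
    are averaged across repetitions.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    y = np.asarray(y, float)
    if len(y) < 25:
        raise ValueError("need >= 25 samples")
    Xv = X.to_numpy(float)
    splitter = ShuffleSplit(n_splits=n_rep, test_size=test_frac, random_state=seed)
    rmse, r2 = np.empty(n_rep), np.empty(n_rep)
    imps = np.empty((n_rep, Xv.shape[1]))
    for k, (tr, va) in enumerate(splitter.split(Xv)):
        rf = RandomForestRegressor(n_estimators=n_trees, max_features=max_features,
                                   random_state=seed + k, n_jobs=1)
        rf.fit(Xv[tr], y[tr])
        pred = rf.predict(Xv[va])
        rmse[k] = float(np.sqrt(np.mean((pred - y[va]) ** 2)))
        ss_tot = float(np.sum((y[va] - y[va].mean()) ** 2))
        r2[k] = 1.0 - float(np.sum((pred - y[va]) ** 2)) / ss_tot if ss_tot > 0 else 0.0
        pi = permutation_importance(rf, Xv[va], y[va], n_repeats=n_perm_repeats,
                                    random_state=seed + k)
        imps[k] = pi.importances_mean
    importance = pd.DataFrame({
        "variable": list(X.columns),
        "importance_mean": imps.mean(axis=0),
        "importance_sd": imps.std(axis=0, ddof=1),
    }).sort_values("importance_mean", ascending=False).reset_index(drop=True)
    return RfCvResult(rmse=rmse, r2=r2, importance=importance,
                      importance_per_rep=imps, variables=list(X.columns))
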