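"""Composite PLS path analysis of productivity, geochemistry and ΔSOC.

The path diagram is the three-node mediation triangle used to attribute
terracing-induced SOC change: plant-productivity change (ΔTPP) acts on
ΔSOC both directly and indirectly through soil geochemistry,

    ΔTPP -> geochemistry -> ΔSOC   and   ΔTPP -> ΔSOC.

Each latent block is summarized by the first principal component of its
standardized indicators (a warning is raised when the first PC explains
less than 75 % of block variance); with single-indicator-per-block
composites the PLS estimation reduces to OLS among standardized composite
scores, so mode and weighting scheme are fully determined.  Coefficient
stability is assessed by bootstrap resampling (SD ``beta_bt``) and k-fold
cross-validation (SD ``beta_cv``); the indirect effect is the product of
the two mediated paths and the total effect is direct + indirect by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import as_rng

logger = logging.getLogger(__name__)

#: Minimum fraction of block variance the first PC should carry.
COMPOSITE_VARIANCE_THRESHOLD = 0.75


def _composite(block: pd.DataFrame, ref_weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Standardized first-PC score of a block; returns (score, weights, var frac)."""
    X = block.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [c for c, s in zip(block.columns, sd) if s == 0]
        raise ValueError(f"degenerate composite: zero-variance indicator(s) {bad}")
    Xs = (X - X.mean(axis=0)) / sd
    if Xs.shape[1] == 1:
        return Xs[:, 0], np.array([1.0]), 1.0
    corr = np.corrcoef(Xs, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    i = int(np.argmax(eigval))
    w = eigvec[:, i]
    if ref_weights is not None:
        if float(w @ ref_weights) < 0:
            w = -w
    elif w.sum() < 0:
        w = -w
    score = Xs @ w
    s = score.std(ddof=1)
    if s == 0:
        raise ValueError("degenerate composite: zero-variance score")
    return score / s, w, float(eigval[i] / Xs.shape[1])


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std(ddof=1)
    if s == 0:
        raise ValueError("degenerate composite: zero variance")
    return (v - v.mean()) / s


def _fit_paths(exog: np.ndarray, med: np.ndarray, out: np.ndarray) -> dict[str, float]:
    """Standardized path coefficients of the mediation triangle by OLS."""
    e, m, o = _standardize(exog), _standardize(med), _standardize(out)
    n = len(e)
    a = float(e @ m / (n - 1)) / float(e @ e / (n - 1))  # med ~ exog
    Z = np.column_stack([np.ones(n), e, m])
    beta, _, _, _ = np.linalg.lstsq(Z, o, rcond=None)
    direct = float(beta[1])
    b = float(beta[2])
    r2_med = 1.0 - float(np.sum((m - a * e) ** 2)) / float(np.sum((m - m.mean()) ** 2))
    resid = o - Z @ beta
    r2_out = 1.0 - float(np.sum(resid**2)) / float(np.sum((o - o.mean()) ** 2))
    return {"a": a, "b": b, "direct": direct, "indirect": a * b,
            "total": direct + a * b, "r2_med": r2_med, "r2_out": r2_out}


class PLSPathModel:
    """Model object for the composite mediation path analysis.

    Parameters
    ----------
    data
        Site-level table (>= 8 observations).
    exog_block, mediator_block
        Column lists defining the ΔTPP and geochemistry indicator blocks.
    outcome
        Name of the ΔSOC column (single indicator).
    """

    def __init__(self, data: pd.DataFrame, exog_block: list[str],
                 mediator_block: list[str], outcome: str):
        if len(data) < 8:
            raise ValueError("path model needs >= 8 site-level observations")
        self.data = data.reset_index(drop=True)
        self.exog_block = list(exog_block)
        self.mediator_block = list(mediator_block)
        self.outcome = outcome

    def _composites(self, df: pd.DataFrame,
                    ref: dict[str, np.ndarray] | None = None) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, float]]:
        scores, weights, varfrac = {}, {}, {}
        for name, cols in (("exog", self.exog_block), ("mediator", self.mediator_block)):
            s, w, v = _composite(df[cols], None if ref is None else ref.get(name))
            scores[name], weights[name], varfrac[name] = s, w, v
        scores["outcome"] = _standardize(df[self.outcome].to_numpy(float))
        varfrac["outcome"] = 1.0
        return scores, weights, varfrac

    def fit(self, n_boot: int = 1000, k_fold: int = 10, seed: int = 0) -> "PLSPathResults":
        if n_boot < 100:
            logger.warning("n_boot < 100 gives unstable bootstrap SDs")
        rng = as_rng(seed)
        df = self.data
        scores, weights, varfrac = self._composites(df)
        for name in ("exog", "mediator"):
            if varfrac[name] < COMPOSITE_VARIANCE_THRESHOLD:
                logger.warning("block %s first PC explains only %.0f%% of variance",
                               name, 100 * varfrac[name])
        point = _fit_paths(scores["exog"], scores["mediator"], scores["outcome"])

        n = len(df)
        keys = ("a", "b", "direct", "indirect", "total", "r2_med", "r2_out")
        boot = {k: [] for k in keys}
        attempts = 0
        while len(boot["a"]) < n_boot and attempts < 20 * n_boot:
            attempts += 1
            idx = rng.integers(0, n, n)
            try:
                s, _, _ = self._composites(df.iloc[idx], ref=weights)
                est = _fit_paths(s["exog"], s["mediator"], s["outcome"])
            except (ValueError, np.linalg.LinAlgError):
                continue  # degenerate resample
            for k in keys:
                boot[k].append(est[k])
        boot_arr = {k: np.asarray(v) for k, v in boot.items()}

        # k-fold CV: coefficient spread over training folds + pooled
        # out-of-fold prediction R2 for the outcome
        perm = rng.permutation(n)
        folds = np.array_split(perm, k_fold)
        cv = {k: [] for k in keys}
        oof_pred = np.full(n, np.nan)
        for f in folds:
            tr = np.setdiff1d(perm, f)
            if len(tr) < 4:
                continue
            try:
                s, w, _ = self._composites(df.iloc[tr], ref=weights)
                est = _fit_paths(s["exog"], s["mediator"], s["outcome"])
            except (ValueError, np.linalg.LinAlgError):
                continue
            for k in keys:
                cv[k].append(est[k])
            # project held-out rows onto the training composites
            def _project(cols, name):
                tr_X = df.iloc[tr][cols].to_numpy(float)
                mu, sd = tr_X.mean(axis=0), tr_X.std(axis=0, ddof=1)
                Xs = (df.iloc[f][cols].to_numpy(float) - mu) / sd
                sc = Xs @ w[name]
                tr_sc = ((tr_X - mu) / sd) @ w[name]
                return (sc - tr_sc.mean()) / tr_sc.std(ddof=1)
            e_hat = _project(self.exog_block, "exog")
            m_hat = _project(self.mediator_block, "mediator")
            oof_pred[f] = est["direct"] * e_hat + est["b"] * m_hat
        cv_arr = {k: np.asarray(v) for k, v in cv.items()}
        o = scores["outcome"]
        ok = np.isfinite(oof_pred)
        r2_cv = (1.0 - float(np.sum((o[ok] - oof_pred[ok]) ** 2))
                 / float(np.sum((o[ok] - o[ok].mean()) ** 2))) if ok.sum() > 2 else np.nan

        def _boot_p(v: np.ndarray) -> float:
            if len(v) == 0:
                return np.nan
            frac = min(np.mean(v > 0), np.mean(v < 0))
            return float(min(1.0, 2.0 * frac))

        paths = pd.DataFrame([
            {"path": "exog->mediator", "beta": point["a"],
             "beta_bt_sd": boot_arr["a"].std(ddof=1), "beta_cv_sd": cv_arr["a"].std(ddof=1),
             "p_boot": _boot_p(boot_arr["a"])},
            {"path": "mediator->outcome", "beta": point["b"],
             "beta_bt_sd": boot_arr["b"].std(ddof=1), "beta_cv_sd": cv_arr["b"].std(ddof=1),
             "p_boot": _boot_p(boot_arr["b"])},
            {"path": "exog->outcome (direct)", "beta": point["direct"],
             "beta_bt_sd": boot_arr["direct"].std(ddof=1),
             "beta_cv_sd": cv_arr["direct"].std(ddof=1),
             "p_boot": _boot_p(boot_arr["direct"])},
        ])
        effects = pd.DataFrame([
            {"variable": "exog", "direct": point["direct"], "indirect": point["indirect"],
             "total": point["total"]},
            {"variable": "mediator", "direct": point["b"], "indirect": 0.0,
             "total": point["b"]},
        ])
        return PLSPathResults(
            model=self, paths=paths, effects=effects,
            r2={"mediator": point["r2_med"], "outcome": point["r2_out"],
                "outcome_boot_sd": float(boot_arr["r2_out"].std(ddof=1)) if len(boot_arr["r2_out"]) > 1 else np.nan,
                "outcome_cv": r2_cv},
            composite_variance=varfrac, boot=boot_arr, cv=cv_arr, seed=seed)


@dataclass
class PLSPathResults:
    """Fitted composite path model with bootstrap / CV stability measures."""

    model: PLSPathModel
    paths: pd.DataFrame
    effects: pd.DataFrame
    r2: dict
    composite_variance: dict
    boot: dict
    cv: dict
    seed: int

    @property
    def direct_effect(self) -> float:
        return float(self.effects.loc[self.effects["variable"] == "exog", "direct"].iloc[0])

    @property
    def indirect_effect(self) -> float:
        return float(self.effects.loc[self.effects["variable"] == "exog", "indirect"].iloc[0])

    @property
    def total_effect(self) -> float:
        return float(self.effects.loc[self.effects["variable"] == "exog", "total"].iloc[0])

    def summary(self) -> str:
        lines = [
            "Composite PLS path model: ΔTPP -> geochemistry -> ΔSOC",
            "=" * 60,
            self.paths.to_string(index=False, float_format=lambda v: f"{v:7.3f}"),
            "",
            self.effects.to_string(index=False, float_format=lambda v: f"{v:7.3f}"),
            "",
            f"R2 mediator = {self.r2['mediator']:.2f}; "
            f"R2 outcome = {self.r2['outcome']:.2f} "
            f"(bootstrap SD {self.r2['outcome_boot_sd']:.3f}, "
            f"CV {self.r2['outcome_cv']:.2f})",
            "First-PC block variance: "
            + ", ".join(f"{k} {100 * v:.0f}%" for k, v in self.composite_variance.items()),
        ]
        return "\n".join(lines)
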