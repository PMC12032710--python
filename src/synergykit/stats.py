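"""Support-condition statistics on synergy muscle weightings.

For each temporal synergy the 30-channel weighting vectors are reduced to 16
responses (bilateral left/right means plus erector spinae and rectus
abdominis), vertically stacked across trials and muscles, and modeled with a
linear mixed model with a participant random intercept, fitted by maximum
likelihood:

    stage 1:  weighting ~ LT + FS + (1 | participant)      (dummy coding,
              run twice: UA and LT as reference, Bonferroni over 2 * n tests)
    stage 2:  weighting ~ (LT + FS) * muscle + (1 | participant)
              (muscle effect-coded with rectus abdominis as reference level;
              only if stage 1 is significant, at most 3 follow-up tests)

Wald t statistics use residual degrees of freedom (observations minus
fixed-effect rank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .datatypes import SUPPORTS, TrialMeta
from .muscles import MUSCLE16_NAMES


class SingleParticipantError(ValueError):
    """Random intercept unidentifiable with one participant; use a
    fixed-effects model instead."""


def average_bilateral(weightings30: np.ndarray) -> np.ndarray:
    """Reduce a 30-channel weighting vector to 16 muscles.

    The 28 bilateral channels (left/right adjacent) are averaged pairwise in
    the fixed muscle order; ES and RA pass through, RA last (reference level).
    """
    w = np.asarray(weightings30, dtype=float)
    if w.shape != (30,):
        raise ValueError(f"expected a 30-vector, got shape {w.shape}")
    bilateral = 0.5 * (w[0:28:2] + w[1:28:2])
    return np.concatenate([bilateral, w[28:30]])


def build_observation_table(
    observations: list[tuple[TrialMeta, np.ndarray]]
) -> pd.DataFrame:
    """Stack per-trial 30-channel weighting vectors into the long response
    table: 16 rows per trial (response, participant, support, muscle, trial)."""
    rows = []
    for trial_id, (meta, w30) in enumerate(observations):
        w16 = average_bilateral(w30)
        for muscle, value in zip(MUSCLE16_NAMES, w16):
            rows.append(
                dict(
                    response=float(value),
                    participant=meta.participant,
                    support=meta.support,
                    muscle=muscle,
                    trial=trial_id,
                )
            )
    table = pd.DataFrame(rows)
    table["muscle"] = pd.Categorical(table["muscle"], categories=MUSCLE16_NAMES)
    return table


@dataclass
class LMMFit:
    model: str                      # 'support-only' | 'support-x-muscle'
    reference_support: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    random_intercept_var: float
    residual_var: float
    df_resid: float
    alpha_corrected: float | None = None
    converged: bool = True
    result: object = field(default=None, repr=False)

    def coef(self, name_fragment: str) -> pd.Series:
        hits = [ix for ix in self.params.index if name_fragment in ix]
        if not hits:
            raise KeyError(f"no coefficient matches {name_fragment!r}")
        return self.params[hits]


def _add_support_dummies(table: pd.DataFrame, reference: str) -> tuple[pd.DataFrame, list[str]]:
    if reference not in SUPPORTS:
        raise ValueError(f"reference support must be one of {SUPPORTS}")
    others = [s for s in SUPPORTS if s != reference]
    t = table.copy()
    names = []
    for s in others:
        col = f"sup_{s}"
        t[col] = (t["support"] == s).astype(float)
        names.append(col)
    return t, names


def _fit_ml(formula: str, table: pd.DataFrame):
    if table["participant"].nunique() < 2:
        raise SingleParticipantError(
            "only one participant: the random intercept is unidentifiable; "
            "fit a fixed-effects (OLS) model instead"
        )
    model = smf.mixedlm(formula, table, groups=table["participant"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=False, method="lbfgs", maxiter=500)
    return model, result


def _wrap_fit(model, result, kind: str, reference: str) -> LMMFit:
    k_fe = model.exog.shape[1]
    df = result.nobs - k_fe
    fe = result.fe_params
    bse = result.bse_fe
    tvals = fe / bse
    pvals = pd.Series(
        2.0 * sps.t.sf(np.abs(tvals.values), df), index=fe.index
    )
    return LMMFit(
        model=kind,
        reference_support=reference,
        params=fe,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        random_intercept_var=float(np.asarray(result.cov_re).ravel()[0]),
        residual_var=float(result.scale),
        df_resid=float(df),
        converged=bool(getattr(result, "converged", True)),
        result=result,
    )


def fit_support_lmm(table: pd.DataFrame, reference_support: str = "UA") -> LMMFit:
    """Stage-1 model: support fixed effects (reference coding) + participant
    random intercept, maximum-likelihood estimation."""
    present = set(table["support"].unique())
    if len(present) < 2:
        raise ValueError("need at least 2 support levels present")
    t, dummies = _add_support_dummies(table, reference_support)
    formula = "response ~ " + " + ".join(dummies)
    model, result = _fit_ml(formula, t)
    return _wrap_fit(model, result, "support-only", reference_support)


def fit_muscle_interaction_lmm(
    table: pd.DataFrame, reference_support: str = "UA"
) -> LMMFit:
    """Stage-2 model: adds effect-coded muscle main effects (RA as the omitted
    reference level) and support x muscle interactions."""
    t, dummies = _add_support_dummies(table, reference_support)
    sup = "(" + " + ".join(dummies) + ")"
    formula = f"response ~ {sup} * C(muscle, Sum(omit='RA'))"
    model, result = _fit_ml(formula, t)
    return _wrap_fit(model, result, "support-x-muscle", reference_support)


def adjust_alpha(base_alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-corrected significance level."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return base_alpha / n_tests


@dataclass
class ResidualDiagnostics:
    skewness: float
    normality_stat: float
    normality_p: float
    hetero_spearman_rho: float
    hetero_p: float


def residual_diagnostics(fit: LMMFit) -> ResidualDiagnostics:
    """Advisory residual summaries: skewness, omnibus normality, and a
    Spearman association between |residual| and fitted values
    (heteroscedasticity screen). Never gates the analysis."""
    if fit.result is None:
        raise ValueError("fit carries no underlying model result")
    # conditional residuals where the random-effect variance allows their
    # prediction; marginal residuals otherwise
    model = fit.result.model
    fitted = np.asarray(model.exog @ fit.result.fe_params)
    try:
        re = fit.result.random_effects
        groups = np.asarray(model.groups)
        fitted = fitted + np.array([float(re[g].iloc[0]) for g in groups])
    except (ValueError, np.linalg.LinAlgError):
        pass
    resid = np.asarray(model.endog) - fitted
    stat, p = sps.normaltest(resid)
    rho, hp = sps.spearmanr(np.abs(resid), fitted)
    return ResidualDiagnostics(
        skewness=float(sps.skew(resid)),
        normality_stat=float(stat),
        normality_p=float(p),
        hetero_spearman_rho=float(rho),
        hetero_p=float(hp),
    )


@dataclass
class SynergySupportResult:
    synergy: int
    stage1: dict[str, LMMFit]
    significant: bool
    alpha_stage1: float
    stage2: dict[str, LMMFit] = field(default_factory=dict)
    alpha_stage2: float | None = None


def run_support_analysis(
    observations_per_synergy: list[list[tuple[TrialMeta, np.ndarray]]],
    *,
    base_alpha: float = 0.05,
) -> list[SynergySupportResult]:
    """Two-stage procedure for all synergies of one strategy.

    Stage 1 fits each synergy's stacked weighting table twice (UA and LT
    reference), with Bonferroni correction over 2 x n_synergies tests. Where
    any support coefficient is significant, stage 2 adds the muscle
    interaction (alpha corrected for at most 3 pairwise follow-ups).
    """
    n_syn = len(observations_per_synergy)
    alpha1 = adjust_alpha(base_alpha, 2 * n_syn)
    out = []
    for syn, obs in enumerate(observations_per_synergy):
        table = build_observation_table(obs)
        stage1 = {
            ref: fit_support_lmm(table, reference_support=ref)
            for ref in ("UA", "LT")
        }
        sig = any(
            fit.pvalues[[ix for ix in fit.pvalues.index if ix.startswith("sup_")]]
            .lt(alpha1)
            .any()
            for fit in stage1.values()
        )
        res = SynergySupportResult(
            synergy=syn, stage1=stage1, significant=bool(sig), alpha_stage1=alpha1
        )
        if sig:
            res.alpha_stage2 = adjust_alpha(base_alpha, 3)
            res.stage2 = {"UA": fit_muscle_interaction_lmm(table, "UA")}
        out.append(res)
    return out
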