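"""Model comparison, fit indices and the model-building ladder.

Nested models are compared with likelihood-ratio tests; global fit is
summarized by the chi-square against the saturated model together with
CFI, TLI, SRMR and RMSEA (90% interval from the noncentral chi-square).
Adequate fit follows the conventional thresholds CFI/TLI >= 0.95 and
RMSEA/SRMR <= 0.05.

The univariate model ladder fits four specifications of increasing
complexity — (1) autoregressive residuals only, (2) + per-burst random
intercepts, (3) + per-burst fixed slopes, (4) + random slopes — and stops
escalating as soon as the likelihood-ratio test no longer prefers the
more complex model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .estimation import (
    FitOptions,
    FitResult,
    MomentFit,
    PanelData,
    baseline_fit,
    fit,
    saturated_fit,
)
from .model_spec import ModelSpec, build_univariate

__all__ = ["ComparisonResult", "FitIndices", "lrt", "fit_indices", "build_ladder", "LadderResult"]


@dataclass
class ComparisonResult:
    """Likelihood-ratio comparison of two nested fits."""

    model_a: object  # restricted
    model_b: object  # full
    lr_statistic: float
    df_diff: int
    p_value: float
    preferred: object
    prefer_full: bool


def lrt(fit_restricted, fit_full, alpha: float = 0.05) -> ComparisonResult:
    """Likelihood-ratio test of a restricted against a nested full model.

    The statistic is 2(ll_full - ll_restricted), referred to the
    chi-square with df equal to the difference in free parameters; the
    full model is preferred when p < ``alpha``. Errors when the models are
    not nested by parameter count or were fit to different data.
    """
    if (
        fit_restricted.data_hash is not None
        and fit_full.data_hash is not None
        and fit_restricted.data_hash != fit_full.data_hash
    ):
        raise ValueError("likelihood-ratio test requires fits to the same data")
    df_diff = fit_full.n_free - fit_restricted.n_free
    if df_diff <= 0:
        raise ValueError(
            "models are not nested with the full model larger "
            f"(df_diff = {df_diff}); cannot form a likelihood-ratio test"
        )
    stat = 2.0 * (fit_full.loglik - fit_restricted.loglik)
    if stat < -1e-6 * max(1.0, abs(fit_full.loglik)):
        raise ValueError(
            f"full model fits worse than the restricted one (statistic {stat:.3g}); "
            "check convergence or nesting"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df_diff)) if stat > 0 else 1.0
    prefer_full = p < alpha
    return ComparisonResult(
        model_a=fit_restricted,
        model_b=fit_full,
        lr_statistic=float(stat),
        df_diff=int(df_diff),
        p_value=p,
        preferred=fit_full if prefer_full else fit_restricted,
        prefer_full=prefer_full,
    )


@dataclass
class FitIndices:
    chisq: float
    df: int
    p_value: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    adequate: bool

    def to_dict(self) -> dict:
        return {
            "chisq": self.chisq,
            "df": self.df,
            "p_value": self.p_value,
            "cfi": self.cfi,
            "tli": self.tli,
            "rmsea": self.rmsea,
            "rmsea_ci_low": self.rmsea_ci[0],
            "rmsea_ci_high": self.rmsea_ci[1],
            "srmr": self.srmr,
            "adequate": self.adequate,
        }


def _rmsea_interval(T: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """90% RMSEA interval by inverting the noncentral chi-square."""
    lo_p = (1.0 + level) / 2.0  # 0.95
    hi_p = (1.0 - level) / 2.0  # 0.05

    def bound(target):
        # find ncp with P(chi2_df(ncp) <= T) = target
        f = lambda lam: stats.ncx2.cdf(T, df, lam) - target
        if f(0.0) < 0:
            return 0.0
        hi = max(T, 1.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 2.0
        if f(hi) > 0:
            return hi
        return optimize.brentq(f, 0.0, hi, xtol=1e-8)

    lam_lo = bound(lo_p)
    lam_hi = bound(hi_p)
    lo = np.sqrt(max(lam_lo, 0.0) / (df * n))
    hi = np.sqrt(max(lam_hi, 0.0) / (df * n))
    return float(lo), float(hi)


def fit_indices(
    result: FitResult,
    saturated: MomentFit | None = None,
    baseline: MomentFit | None = None,
    data=None,
    n: int | None = None,
    cfi_threshold: float = 0.95,
    rmsea_threshold: float = 0.05,
    srmr_threshold: float = 0.05,
) -> FitIndices:
    """Chi-square, CFI, TLI, RMSEA (with 90% CI) and SRMR for one fit.

    The saturated and baseline (independence, free means and variances)
    reference fits are computed from ``data`` when not supplied. The
    SRMR averages squared standardized residual moments, mean structure
    included; RMSEA uses n = number of persons.
    """
    if saturated is None or baseline is None:
        if data is None:
            raise ValueError("supply data or both reference fits")
        if saturated is None:
            saturated = saturated_fit(data)
        if baseline is None:
            baseline = baseline_fit(data)
    n = int(n if n is not None else result.n_persons)

    T = max(2.0 * (saturated.loglik - result.loglik), 0.0)
    df = result.df
    T0 = max(2.0 * (saturated.loglik - baseline.loglik), 0.0)
    df0 = baseline.df
    p_value = float(stats.chi2.sf(T, df)) if df > 0 else float("nan")

    num = max(T - df, 0.0)
    den = max(T0 - df0, T - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    if df0 > 0 and df > 0 and (T0 / df0) != 1.0:
        tli = ((T0 / df0) - (T / df)) / ((T0 / df0) - 1.0)
        tli = min(tli, 1.0)
    else:
        tli = float("nan")
    if df == 0:
        raise ZeroDivisionError("RMSEA undefined for a saturated (df = 0) model")
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * n)))
    ci = _rmsea_interval(T, df, n)

    s_mean, s_cov = saturated.mean, saturated.cov
    m_mean, m_cov = result.implied_mean, result.implied_cov
    sd = np.sqrt(np.diag(s_cov))
    p = len(sd)
    iu = np.triu_indices(p)
    cov_resid = (s_cov - m_cov)[iu] / np.outer(sd, sd)[iu]
    mean_resid = (s_mean - m_mean) / sd
    n_moments = p * (p + 1) // 2 + p
    srmr = float(np.sqrt((np.sum(cov_resid**2) + np.sum(mean_resid**2)) / n_moments))

    adequate = bool(
        cfi >= cfi_threshold
        and tli >= cfi_threshold
        and rmsea <= rmsea_threshold
        and srmr <= srmr_threshold
    )
    return FitIndices(
        chisq=float(T),
        df=int(df),
        p_value=p_value,
        cfi=float(cfi),
        tli=float(tli),
        rmsea=rmsea,
        rmsea_ci=ci,
        srmr=srmr,
        adequate=adequate,
    )


@dataclass
class LadderResult:
    trail: list  # (level, ModelSpec, FitResult)
    comparisons: list  # ComparisonResult or ("dominance", ...) records
    selected_level: int
    selected_spec: ModelSpec
    selected_fit: FitResult


def build_ladder(
    construct: str,
    data,
    bursts=None,
    n_waves: int | None = None,
    alpha: float = 0.05,
    options: FitOptions | None = None,
    max_level: int = 4,
) -> LadderResult:
    """Fit the univariate model ladder and select by sequential comparison.

    Levels 2 vs 3 and 3 vs 4 are compared by likelihood-ratio test
    (escalate when p < ``alpha``). Level 1 (free per-wave means, no random
    effects) is not parametrically nested in level 2 (burst-level means
    carried by random intercepts), so that step escalates by dominance:
    level 2 is preferred when it attains a higher log-likelihood despite
    its smaller parameter count. Non-convergence halts the ladder.
    """
    if not isinstance(data, PanelData):
        data = PanelData(data)
    if n_waves is None:
        n_waves = sum(1 for c in data.columns if c.startswith(construct))
    trail = []
    comparisons = []
    selected = None
    for level in range(1, max_level + 1):
        spec = build_univariate(construct, level, n_waves, bursts)
        res = fit(spec, data.select(spec.observed_vars), options=options)
        if not res.converged:
            raise RuntimeError(
                f"ladder halted: level-{level} model did not converge "
                f"(gradient norm {res.gradient_norm:.3g}; {res.message})"
            )
        trail.append((level, spec, res))
        if level == 1:
            selected = (level, spec, res)
            continue
        prev_level, prev_spec, prev_res = selected
        if level == 2:
            prefer_new = res.loglik > prev_res.loglik
            comparisons.append(
                {
                    "step": f"{prev_level} vs {level}",
                    "method": "dominance",
                    "ll_restricted": prev_res.loglik,
                    "ll_full": res.loglik,
                    "prefer_full": bool(prefer_new),
                }
            )
        else:
            comp = lrt(prev_res, res, alpha=alpha)
            comparisons.append(comp)
            prefer_new = comp.prefer_full
        if prefer_new:
            selected = (level, spec, res)
        else:
            break
    level, spec, res = selected
    return LadderResult(
        trail=trail,
        comparisons=comparisons,
        selected_level=level,
        selected_spec=spec,
        selected_fit=res,
    )
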