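"""Measurement-burst panel generator with LCM-SR structure.

Emulates a two-burst biweekly design in community-dwelling older adults:
a bounded frailty index (FI, deficit-accumulation scale) and a discrete
3-9 loneliness sum score (LS) observed over two bursts of seven biweekly
waves set one year apart, with monotone attrition. The generative model
is the structural recursion itself (random intercepts and fixed slopes
plus autoregressive / cross-lagged / cross-correlated latent residuals),
written forward in wave order and deliberately independent of the RAM
matrix algebra used for estimation — agreement of the two is a
cross-module consistency oracle, not a tautology.

Defaults reproduce the study conditions the package is tested under:
426 persons; FI wave means ~0.18 (burst 1) and ~0.20 (burst 2) with SD
~0.14; LS means ~3.4-3.5; very high between-person stability (intercept
correlations ~0.9 within construct, ~0.55 across); weak within-person
autoregression (0.2 for FI, 0.1 for LS); no cross-lagged effects; a
within-wave innovation correlation of 0.15; and per-wave retention
shaped like the observed wave counts (426 down to 202).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import score_frailty_index

__all__ = [
    "BivariateParameters",
    "GeneratorConfig",
    "default_parameters",
    "default_retention",
    "simulate_panel",
    "simulate_items",
    "dropout_mask",
    "to_long",
    "to_wide",
]

#: per-wave participant counts the default retention curve is scaled from
DEFAULT_WAVE_COUNTS = (426, 419, 419, 410, 406, 407, 406, 378, 350, 356, 334, 320, 290, 202)


def default_retention() -> np.ndarray:
    counts = np.asarray(DEFAULT_WAVE_COUNTS, dtype=float)
    return counts / counts[0]


@dataclass
class BivariateParameters:
    """Named generating parameters of the canonical bivariate model.

    Residual variances are the wave-1 marginal variance followed by
    innovation variances for waves 2..T (per construct); ``lambda_`` holds
    within-wave cross-construct residual covariances (wave 1: marginal,
    later waves: innovation covariances). ``zeta`` holds the 6 intercept
    covariances in the order (FI1,FI2), (FI1,LS1), (FI1,LS2), (FI2,LS1),
    (FI2,LS2), (LS1,LS2).
    """

    alpha: np.ndarray  # FI -> FI autoregressions, length T-1
    beta: np.ndarray  # LS -> LS autoregressions
    gamma: np.ndarray  # FI -> LS cross-lags
    delta: np.ndarray  # LS -> FI cross-lags
    lambda_: np.ndarray  # within-wave residual covariances, length T
    zeta: np.ndarray  # intercept covariances, length 6
    mu_RI: np.ndarray  # intercept means (FI1, FI2, LS1, LS2)
    mu_S: np.ndarray  # LS slope means per burst
    var_RI: np.ndarray  # intercept variances (FI1, FI2, LS1, LS2)
    resid_var_fi: np.ndarray  # length T
    resid_var_ls: np.ndarray  # length T

    def as_label_dict(self) -> dict[str, float]:
        """Map onto the free-parameter labels of the canonical bivariate spec."""
        T = len(self.lambda_)
        vals: dict[str, float] = {}
        for t in range(1, T):
            vals[f"ar_FI_{t}"] = float(self.alpha[t - 1])
            vals[f"ar_LS_{t}"] = float(self.beta[t - 1])
            vals[f"cl_FI_LS_{t}"] = float(self.gamma[t - 1])
            vals[f"cl_LS_FI_{t}"] = float(self.delta[t - 1])
        for t in range(1, T + 1):
            vals[f"resvar_FI_{t}"] = float(self.resid_var_fi[t - 1])
            vals[f"resvar_LS_{t}"] = float(self.resid_var_ls[t - 1])
            vals[f"wcov_FI_LS_{t}"] = float(self.lambda_[t - 1])
        for b in (1, 2):
            vals[f"imean_FI_{b}"] = float(self.mu_RI[b - 1])
            vals[f"imean_LS_{b}"] = float(self.mu_RI[1 + b])
            vals[f"ivar_FI_{b}"] = float(self.var_RI[b - 1])
            vals[f"ivar_LS_{b}"] = float(self.var_RI[1 + b])
            vals[f"smean_LS_{b}"] = float(self.mu_S[b - 1])
        for z, pair in zip(
            self.zeta,
            ("FI1_FI2", "FI1_LS1", "FI1_LS2", "FI2_LS1", "FI2_LS2", "LS1_LS2"),
        ):
            vals[f"icov_{pair}"] = float(z)
        return vals

    def theta_for(self, ram) -> np.ndarray:
        """Parameter vector ordered for a compiled canonical bivariate model."""
        vals = self.as_label_dict()
        return np.array([vals[lab] for lab in ram.labels])

    def intercept_cov(self) -> np.ndarray:
        V = np.diag(self.var_RI).astype(float)
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for z, (i, j) in zip(self.zeta, pairs):
            V[i, j] = V[j, i] = z
        return V

    def validate(self, n_waves: int) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            if len(getattr(self, name)) != n_waves - 1:
                raise ValueError(f"{name} must have length {n_waves - 1}")
        if len(self.lambda_) != n_waves:
            raise ValueError("lambda_ must have length n_waves")
        if len(self.resid_var_fi) != n_waves or len(self.resid_var_ls) != n_waves:
            raise ValueError("residual variances must have length n_waves")
        if np.any(self.resid_var_fi <= 0) or np.any(self.resid_var_ls <= 0):
            raise ValueError("residual variances must be positive")
        if np.any(self.var_RI <= 0):
            raise ValueError("intercept variances must be positive")
        V = self.intercept_cov()
        if np.linalg.eigvalsh(V).min() <= 0:
            raise ValueError("intercept covariance matrix is not positive definite")
        for t in range(n_waves):
            c = self.lambda_[t]
            if c * c >= self.resid_var_fi[t] * self.resid_var_ls[t]:
                raise ValueError(f"inadmissible within-wave covariance at wave {t + 1}")


def default_parameters(
    n_waves: int = 14,
    innovation_correlation: float = 0.15,
) -> BivariateParameters:
    """Generating values at the magnitudes of the study conditions."""
    T = n_waves
    alpha = np.full(T - 1, 0.20)
    beta = np.full(T - 1, 0.10)
    gamma = np.zeros(T - 1)
    delta = np.zeros(T - 1)
    v_fi = np.empty(T)
    v_ls = np.empty(T)
    v_fi[0] = 0.003
    v_fi[1:] = 0.003 * (1.0 - 0.20**2)
    v_ls[0] = 0.16
    v_ls[1:] = 0.16 * (1.0 - 0.10**2)
    lam = innovation_correlation * np.sqrt(v_fi * v_ls)
    var_RI = np.array([0.016, 0.016, 0.45, 0.45])
    corr = np.array([0.94, 0.57, 0.58, 0.52, 0.53, 0.92])
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    zeta = np.array(
        [corr[k] * np.sqrt(var_RI[i] * var_RI[j]) for k, (i, j) in enumerate(pairs)]
    )
    return BivariateParameters(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        delta=delta,
        lambda_=lam,
        zeta=zeta,
        mu_RI=np.array([0.18, 0.20, 3.39, 3.51]),
        mu_S=np.array([0.02, -0.01]),
        var_RI=var_RI,
        resid_var_fi=v_fi,
        resid_var_ls=v_ls,
    )


@dataclass
class GeneratorConfig:
    """Configuration of one simulated burst panel."""

    n_persons: int = 426
    n_waves: int = 14
    bursts: tuple = ((1, 2, 3, 4, 5, 6, 7), (8, 9, 10, 11, 12, 13, 14))
    theta: BivariateParameters | None = None
    retention: np.ndarray | None = None  # per-wave observation probabilities
    monotone_dropout: bool = True
    discretize_ls: bool = False  # round-and-clip LS to integers 3..9
    clip_fi: bool = False  # clip FI to [0, 1]
    seed: int = 0

    def resolve(self) -> "GeneratorConfig":
        theta = self.theta if self.theta is not None else default_parameters(self.n_waves)
        theta.validate(self.n_waves)
        retention = (
            np.asarray(self.retention, dtype=float)
            if self.retention is not None
            else (default_retention() if self.n_waves == 14 else np.ones(self.n_waves))
        )
        if len(retention) != self.n_waves:
            raise ValueError("retention must have one probability per wave")
        if np.any(retention <= 0) or np.any(retention > 1):
            raise ValueError("retention probabilities must lie in (0, 1]")
        flat = [w for b in self.bursts for w in b]
        if sorted(flat) != list(range(1, self.n_waves + 1)):
            raise ValueError("bursts must partition 1..n_waves")
        out = GeneratorConfig(**{**self.__dict__})
        out.theta = theta
        out.retention = retention
        return out


def dropout_mask(
    n_persons: int,
    retention: np.ndarray,
    monotone: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Boolean observation mask (True = observed), one row per person.

    Monotone mode draws a single dropout time per person so that once a
    wave is missed all later waves are missed, with per-wave marginal
    observation probabilities equal to the running minimum of
    ``retention``; non-monotone mode observes waves independently.
    """
    rng = rng if rng is not None else np.random.default_rng()
    retention = np.asarray(retention, dtype=float)
    if monotone:
        surv = np.minimum.accumulate(retention)
        u = rng.random(n_persons)
        return u[:, None] <= surv[None, :]
    return rng.random((n_persons, len(retention))) <= retention[None, :]


def simulate_panel(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate a wide person x wave panel (columns FI1..FIT, LS1..LST).

    Draws the growth factors from their joint normal, then generates the
    latent residual series forward in wave order with correlated
    cross-construct innovations, applies the burst growth structure,
    attrition, and the optional discretization/clipping.
    """
    cfg = config.resolve()
    th = cfg.theta
    T = cfg.n_waves
    n = cfg.n_persons
    rng = np.random.default_rng(cfg.seed)

    V = th.intercept_cov()
    ri = rng.multivariate_normal(th.mu_RI, V, size=n, method="cholesky")
    # burst membership and slope coding (0, 1, 2, ... within each burst)
    burst_of = np.empty(T, dtype=int)
    coding = np.empty(T)
    for b, waves in enumerate(cfg.bursts):
        for j, w in enumerate(waves):
            burst_of[w - 1] = b
            coding[w - 1] = j

    res_fi = np.empty((n, T))
    res_ls = np.empty((n, T))
    for t in range(T):
        if t == 0:
            cov = np.array(
                [[th.resid_var_fi[0], th.lambda_[0]], [th.lambda_[0], th.resid_var_ls[0]]]
            )
            innov = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
            res_fi[:, 0] = innov[:, 0]
            res_ls[:, 0] = innov[:, 1]
        else:
            cov = np.array(
                [[th.resid_var_fi[t], th.lambda_[t]], [th.lambda_[t], th.resid_var_ls[t]]]
            )
            innov = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
            res_fi[:, t] = (
                th.alpha[t - 1] * res_fi[:, t - 1]
                + th.delta[t - 1] * res_ls[:, t - 1]
                + innov[:, 0]
            )
            res_ls[:, t] = (
                th.beta[t - 1] * res_ls[:, t - 1]
                + th.gamma[t - 1] * res_fi[:, t - 1]
                + innov[:, 1]
            )

    fi = ri[:, burst_of] + res_fi  # FI intercepts are columns 0, 1
    ls = ri[:, 2 + burst_of] + th.mu_S[burst_of][None, :] * coding[None, :] + res_ls

    if cfg.clip_fi:
        fi = np.clip(fi, 0.0, 1.0)
    if cfg.discretize_ls:
        ls = np.clip(np.rint(ls), 3.0, 9.0)

    mask = dropout_mask(n, cfg.retention, cfg.monotone_dropout, rng)
    fi = np.where(mask, fi, np.nan)
    ls = np.where(mask, ls, np.nan)

    cols = {f"FI{t+1}": fi[:, t] for t in range(T)}
    cols.update({f"LS{t+1}": ls[:, t] for t in range(T)})
    out = pd.DataFrame(cols)
    out.insert(0, "person_id", np.arange(1, n + 1))
    out.attrs["seed"] = cfg.seed
    return out


def simulate_items(
    fi_values: np.ndarray,
    n_items: int = 37,
    rng: np.random.Generator | None = None,
    valid_fraction: float = 1.0,
) -> pd.DataFrame:
    """Binary deficit items whose recomputed FI matches the input.

    For each FI value f, round(f * n_items) randomly placed items are set
    to 1, so the rescored index differs from f by at most 1/(2 n_items).
    ``valid_fraction`` < 1 marks a random share of items missing per row
    (e.g. to exercise the 80% validity rule downstream); the deficits are
    placed among the valid items so the valid-item mean is preserved.
    """
    rng = rng if rng is not None else np.random.default_rng()
    f = np.asarray(fi_values, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("FI values must lie in [0, 1]")
    n_valid = int(round(valid_fraction * n_items))
    if n_valid < 1:
        raise ValueError("valid_fraction leaves no valid items")
    rows = np.zeros((len(f), n_items))
    for r, val in enumerate(f):
        valid_idx = rng.permutation(n_items)[:n_valid]
        k = int(round(val * n_valid))
        ones = rng.permutation(valid_idx)[:k]
        rows[r, :] = np.nan
        rows[r, valid_idx] = 0.0
        rows[r, ones] = 1.0
    return pd.DataFrame(rows, columns=[f"item{i+1}" for i in range(n_items)])


# ---------------------------------------------------------------------------
# long <-> wide reshaping helpers


def to_long(wide: pd.DataFrame, variables: tuple[str, ...] = ("FI", "LS")) -> pd.DataFrame:
    """Wide (FI1..LS14) to long (person_id, wave, fi, ls) format."""
    if "person_id" not in wide.columns:
        wide = wide.copy()
        wide.insert(0, "person_id", np.arange(1, len(wide) + 1))
    waves = sorted(
        {int(c[len(variables[0]):]) for c in wide.columns if c.startswith(variables[0])}
    )
    records = []
    for t in waves:
        rec = {"person_id": wide["person_id"], "wave": t}
        for v in variables:
            col = f"{v}{t}"
            if col in wide.columns:
                rec[v.lower()] = wide[col]
        records.append(pd.DataFrame(rec))
    long = pd.concat(records, ignore_index=True)
    return long.sort_values(["person_id", "wave"]).reset_index(drop=True)


def to_wide(long: pd.DataFrame, variables: tuple[str, ...] = ("fi", "ls")) -> pd.DataFrame:
    """Long (person_id, wave, fi, ls) to wide (FI1..LS14) format."""
    waves = sorted(long["wave"].unique())
    out = None
    for v in variables:
        wide = long.pivot(index="person_id", columns="wave", values=v)
        wide.columns = [f"{v.upper()}{int(t)}" for t in wide.columns]
        wide = wide[[f"{v.upper()}{int(t)}" for t in waves]]
        out = wide if out is None else out.join(wide)
    return out.reset_index()
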