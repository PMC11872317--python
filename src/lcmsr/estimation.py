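"""FIML estimation of RAM-compiled models with Huber-White sandwich errors.

The likelihood is full-information maximum likelihood under MAR: each
person contributes the multivariate-normal log-density of exactly their
observed variables, evaluated at the sub-mean and sub-covariance implied
for their missingness pattern. Persons are grouped by pattern and the
per-pattern contribution is computed from sufficient statistics (count,
mean, scatter), which is algebraically identical to the per-person sum.

Gradients are analytic. Writing B = (I - A)^-1, G = B restricted to
observed rows, C = B S B', the derivative of the implied moments with
respect to any single matrix cell is a rank-one (plus transpose) update:

* S cell (i, j):  dSigma = g_i g_j' + g_j g_i'        (dmu = 0)
* A cell (a, b):  dSigma = g_a c_b' + c_b g_a',  dmu = g_a (B M)_b
* M cell (i):     dmu    = g_i

with g_i = G[:, i] and c_b = C[b, observed]. The score of the likelihood
with respect to (mu, Sigma) is accumulated over patterns and contracted
against these rank-one terms, so one gradient evaluation costs little
more than one likelihood evaluation. Variances are log-parameterized
internally for positivity; all results are reported on the natural scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .model_spec import ModelSpec, RAMMatrices, compile_spec

__all__ = [
    "PanelData",
    "FitResult",
    "implied_moments",
    "fiml_loglik",
    "fit",
    "sandwich_se",
    "standardize",
    "saturated_fit",
    "baseline_fit",
    "start_values",
    "FitOptions",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# data container


class PanelData:
    """Wide person x variable panel with missingness, grouped by pattern."""

    def __init__(self, data: pd.DataFrame | np.ndarray, columns: Sequence[str] | None = None):
        if isinstance(data, pd.DataFrame):
            self.columns = list(data.columns)
            values = data.to_numpy(dtype=float)
        else:
            values = np.asarray(data, dtype=float)
            if values.ndim != 2:
                raise ValueError("panel data must be 2-d (person x variable)")
            self.columns = (
                list(columns) if columns is not None else [f"y{i}" for i in range(values.shape[1])]
            )
        if values.shape[0] == 0:
            raise ValueError("empty panel: no persons")
        all_missing_rows = np.isnan(values).all(axis=1)
        if all_missing_rows.any():
            raise ValueError(
                f"{all_missing_rows.sum()} person(s) have no observed values; drop them first"
            )
        self.values = values
        self._patterns = None

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_vars(self) -> int:
        return self.values.shape[1]

    def select(self, columns: Sequence[str]) -> "PanelData":
        missing = [c for c in columns if c not in self.columns]
        if missing:
            raise KeyError(f"panel lacks columns {missing}")
        idx = [self.columns.index(c) for c in columns]
        return PanelData(self.values[:, idx], columns=list(columns))

    def patterns(self):
        """Unique missingness patterns with sufficient statistics.

        Returns a list of dicts with keys ``idx`` (observed columns),
        ``rows`` (person rows), ``n``, ``ybar``, ``W`` (ML scatter, /n).
        """
        if self._patterns is None:
            mask = ~np.isnan(self.values)
            uniq, inverse = np.unique(mask, axis=0, return_inverse=True)
            pats = []
            for p in range(uniq.shape[0]):
                rows = np.where(inverse == p)[0]
                idx = np.where(uniq[p])[0]
                Y = self.values[np.ix_(rows, idx)]
                ybar = Y.mean(axis=0)
                D = Y - ybar
                W = D.T @ D / len(rows)
                pats.append({"idx": idx, "rows": rows, "n": len(rows), "ybar": ybar, "W": W, "Y": Y})
            self._patterns = pats
        return self._patterns

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(np.nan_to_num(self.values, nan=-1e30)).tobytes())
        h.update(",".join(self.columns).encode())
        return h.hexdigest()


def _as_panel(data, ram: RAMMatrices) -> PanelData:
    want = [ram.names[i] for i in ram.obs_idx]
    if not isinstance(data, PanelData):
        # bare arrays are taken to be in spec column order
        cols = want if isinstance(data, np.ndarray) else None
        data = PanelData(data, columns=cols)
    if data.columns != want:
        data = data.select(want)
    col_all_nan = np.isnan(data.values).all(axis=0)
    if col_all_nan.any():
        bad = [data.columns[i] for i in np.where(col_all_nan)[0]]
        raise ValueError(f"column(s) entirely missing: {bad}")
    return data


# ---------------------------------------------------------------------------
# likelihood core


def implied_moments(ram: RAMMatrices, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied observed mean vector and covariance matrix."""
    return ram.implied_moments(theta)


def _moment_internals(ram: RAMMatrices, theta: np.ndarray):
    A, S, M = ram.realize(theta)
    k = A.shape[0]
    B = np.linalg.solve(np.eye(k) - A, np.eye(k))
    C = B @ S @ B.T
    BM = B @ M
    obs = ram.obs_idx
    G = B[obs, :]
    mu = BM[obs]
    Sigma = C[np.ix_(obs, obs)]
    return A, S, M, B, C, BM, G, mu, Sigma


def _pattern_loglik(mu, Sigma, patterns):
    """Total FIML log-likelihood from per-pattern sufficient statistics.

    Returns (ll, chol_list) where chol_list caches the per-pattern
    Cholesky factors; ll is -inf when any pattern submatrix is not PD.
    """
    ll = 0.0
    chols = []
    for p in patterns:
        idx = p["idx"]
        Sp = Sigma[np.ix_(idx, idx)]
        try:
            cf = cho_factor(Sp, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf, None
        if not np.all(np.isfinite(cf[0])):
            return -np.inf, None
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        d = p["ybar"] - mu[idx]
        SiW = cho_solve(cf, p["W"], check_finite=False)
        Sid = cho_solve(cf, d, check_finite=False)
        k = len(idx)
        ll += -0.5 * p["n"] * (k * _LOG2PI + logdet + np.trace(SiW) + d @ Sid)
        chols.append(cf)
    return ll, chols


def fiml_loglik(ram: RAMMatrices, theta: np.ndarray, data, grouped: bool = True) -> float:
    """FIML log-likelihood at ``theta``.

    ``grouped=False`` evaluates person-by-person (the naive sum); the
    grouped pattern evaluation is algebraically identical and is the
    default.
    """
    data = _as_panel(data, ram)
    mu, Sigma = ram.implied_moments(theta)
    if grouped:
        ll, _ = _pattern_loglik(mu, Sigma, data.patterns())
        return ll
    ll = 0.0
    for row in data.values:
        idx = np.where(~np.isnan(row))[0]
        Sp = Sigma[np.ix_(idx, idx)]
        try:
            cf = cho_factor(Sp, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        d = row[idx] - mu[idx]
        ll += -0.5 * (len(idx) * _LOG2PI + logdet + d @ cho_solve(cf, d, check_finite=False))
    return ll


def _derivative_terms(ram: RAMMatrices, B, C, BM, G):
    """Rank-one derivative terms per free label.

    Each free matrix cell becomes one term (x, y, c, v, label_index) with
    dSigma = c (x y' + y x') and dmu = v; see module docstring.
    """
    obs = ram.obs_idx
    p = len(obs)
    X, Y, c, V, lab = [], [], [], [], []
    zero = np.zeros(p)
    for li, label in enumerate(ram.labels):
        for mat, i, j in ram.free[label]:
            if mat == "S":
                X.append(G[:, i])
                Y.append(G[:, j])
                c.append(0.5 if i == j else 1.0)
                V.append(zero)
            elif mat == "A":
                X.append(G[:, i])
                Y.append(C[j, obs])
                c.append(1.0)
                V.append(G[:, i] * BM[j])
            else:  # M
                X.append(zero)
                Y.append(zero)
                c.append(0.0)
                V.append(G[:, i])
            lab.append(li)
    return (
        np.asarray(X),
        np.asarray(Y),
        np.asarray(c),
        np.asarray(V),
        np.asarray(lab, dtype=int),
    )


def _loglik_and_grad(ram: RAMMatrices, theta: np.ndarray, data: PanelData):
    """Total log-likelihood and its gradient w.r.t. natural-scale theta."""
    A, S, M, B, C, BM, G, mu, Sigma = _moment_internals(ram, theta)
    patterns = data.patterns()
    ll, chols = _pattern_loglik(mu, Sigma, patterns)
    if not np.isfinite(ll):
        return -np.inf, np.zeros(ram.n_free)
    p = len(mu)
    Dmu = np.zeros(p)
    DSig = np.zeros((p, p))
    for pat, cf in zip(patterns, chols):
        idx = pat["idx"]
        Si = cho_solve(cf, np.eye(len(idx)), check_finite=False)
        d = pat["ybar"] - mu[idx]
        Sid = Si @ d
        Dmu[idx] += pat["n"] * Sid
        E = pat["W"] + np.outer(d, d)
        DSig[np.ix_(idx, idx)] += 0.5 * pat["n"] * (Si @ E @ Si - Si)
    X, Y, c, V, lab = _derivative_terms(ram, B, C, BM, G)
    term = 2.0 * c * np.einsum("tp,pq,tq->t", X, DSig, Y) + V @ Dmu
    grad = np.zeros(ram.n_free)
    np.add.at(grad, lab, term)
    return ll, grad


def _per_person_scores(ram: RAMMatrices, theta: np.ndarray, data: PanelData) -> np.ndarray:
    """Matrix of per-person score vectors (n x n_free), natural scale."""
    A, S, M, B, C, BM, G, mu, Sigma = _moment_internals(ram, theta)
    X, Y, c, V, lab = _derivative_terms(ram, B, C, BM, G)
    n = data.n_persons
    scores_t = np.zeros((n, len(lab)))
    for pat in data.patterns():
        idx = pat["idx"]
        Sp = Sigma[np.ix_(idx, idx)]
        cf = cho_factor(Sp, lower=True, check_finite=False)
        Si = cho_solve(cf, np.eye(len(idx)), check_finite=False)
        R = pat["Y"] - mu[idx]
        U = R @ Si  # per-person scores w.r.t. mu (pattern coordinates)
        Xp, Yp, Vp = X[:, idx], Y[:, idx], V[:, idx]
        xSiY = np.einsum("tp,pq,tq->t", Xp, Si, Yp)
        P = U @ Xp.T
        Q = U @ Yp.T
        contrib = 2.0 * c * 0.5 * (P * Q - xSiY) + U @ Vp.T
        scores_t[pat["rows"], :] = contrib
    scores = np.zeros((n, ram.n_free))
    np.add.at(scores.T, lab, scores_t.T)
    return scores


# ---------------------------------------------------------------------------
# starting values


def start_values(ram: RAMMatrices, data: PanelData) -> np.ndarray:
    """Deterministic admissible start.

    Residual variances start at half the observed variable variances;
    intercept means at burst-specific observed means; intercept variances
    at half the between-person variance of person means; slope variances
    at a tenth of the intercept start; all dynamic parameters, covariances
    and slope means at zero; observed/covariate means and variances at
    their sample values.
    """
    spec = ram.spec
    cols = [ram.names[i] for i in ram.obs_idx]
    df = pd.DataFrame(data.values, columns=cols)
    bursts = (spec.meta.get("bursts") if spec is not None else None) or []
    theta = np.zeros(ram.n_free)

    def col_of(construct, t):
        return f"{construct}{t}"

    for k, label in enumerate(ram.labels):
        parts = label.split("@", 1)[0].split("_")  # strip any group suffix
        fam = parts[0]
        if fam == "resvar":
            c, t = parts[1], int(parts[2])
            v = np.nanvar(df[col_of(c, t)])
            theta[k] = max(0.5 * v, 1e-6)
        elif fam in ("omean", "covmean"):
            c, t = parts[1], int(parts[2])
            theta[k] = np.nanmean(df[col_of(c, t)])
        elif fam == "covvar":
            c, t = parts[1], int(parts[2])
            theta[k] = max(np.nanvar(df[col_of(c, t)]), 1e-6)
        elif fam == "imean":
            c, b = parts[1], int(parts[2])
            waves = bursts[b - 1]
            theta[k] = np.nanmean(df[[col_of(c, t) for t in waves]].to_numpy())
        elif fam == "ivar":
            c, b = parts[1], int(parts[2])
            waves = bursts[b - 1]
            pm = df[[col_of(c, t) for t in waves]].mean(axis=1, skipna=True)
            theta[k] = max(0.5 * float(pm.var(ddof=0)), 1e-6)
        elif fam == "svar":
            c, b = parts[1], int(parts[2])
            waves = bursts[b - 1]
            pm = df[[col_of(c, t) for t in waves]].mean(axis=1, skipna=True)
            theta[k] = max(0.05 * float(pm.var(ddof=0)), 1e-8)
        # ar, cl, wcov, icov, scov, sicov, smean, tvc, ccov start at 0
    return theta


# ---------------------------------------------------------------------------
# fitting


def _minimize_with_restarts(objective, x0, lower, opts):
    """Bounded L-BFGS-B with memory-clearing restarts after ftol stalls.

    Returns (result, projected gradient norm). Restarting from the stall
    point with a fresh quasi-Newton memory recovers progress on poorly
    conditioned plateaus (e.g. covariances of a boundary-zero variance).
    """
    bounds = list(zip(lower, np.full(len(x0), np.inf)))
    # the L-BFGS phase only needs to deliver the Newton polish basin
    lbfgs_opts = {"maxiter": opts.max_iter, "maxfun": 10 * opts.max_iter,
                  "ftol": max(opts.ftol, 1e-9), "gtol": opts.gtol / 10.0,
                  "maxls": 60, "maxcor": 30}

    def projected_gnorm(x):
        _, g = objective(x)
        g = g.copy()
        at_bound = x <= lower + 1e-9
        g[at_bound & (g > 0)] = 0.0  # blocked descent directions
        return float(np.max(np.abs(g)))

    res = optimize.minimize(objective, np.maximum(x0, lower), jac=True,
                            method="L-BFGS-B", bounds=bounds, options=lbfgs_opts)
    gnorm = projected_gnorm(res.x)
    if gnorm >= opts.gtol:
        x, f, gnorm, nit = _newton_polish(objective, res.x, lower, opts)
        if f <= res.fun:
            res.x, res.fun, res.nit = x, f, res.nit + nit
            gnorm = projected_gnorm(res.x)
    return res, gnorm


def _newton_polish(objective, x, lower, opts, max_steps: int = 8):
    """Damped Newton iterations on the preconditioned internal scale.

    The quasi-Newton phase stalls on badly conditioned directions (highly
    correlated intercept variances/covariances); a handful of Newton steps
    with an explicit finite-difference Hessian of the analytic gradient
    finishes the job. Eigenvalues are floored to keep steps descent
    directions; bound-violating components are clipped.
    """
    k = len(x)
    f, g = objective(x)
    nit = 0
    for _ in range(max_steps):
        active = x <= lower + 1e-9
        gp = g.copy()
        gp[active & (gp > 0)] = 0.0
        if np.max(np.abs(gp)) < opts.gtol:
            break
        H = np.zeros((k, k))
        h = 1e-4
        for j in range(k):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            _, gjp = objective(xp)
            _, gjm = objective(xm)
            H[:, j] = (gjp - gjm) / (2 * h)
        H = (H + H.T) / 2.0
        w, V = np.linalg.eigh(H)
        w = np.maximum(w, max(1e-8, 1e-6 * np.abs(w).max()))
        step = -(V @ ((V.T @ g) / w))
        norm = np.max(np.abs(step))
        if norm > 10.0:  # cap steps exploding along near-null directions
            step *= 10.0 / norm
        # backtracking line search with bound clipping
        improved = False
        for candidate in (step, -g):
            t = 1.0
            for _ in range(30):
                xn = np.maximum(x + t * candidate, lower)
                fn, gn = objective(xn)
                if fn <= f - 1e-14 * abs(f):
                    x, f, g = xn, fn, gn
                    improved = True
                    break
                t *= 0.5
            if improved:
                break
        nit += 1
        if not improved:
            break
    return x, f, np.max(np.abs(g)), nit


@dataclass
class FitOptions:
    gtol: float = 1e-5  # max |gradient| of the mean log-likelihood, internal scale
    ftol: float = 1e-11  # relative objective change
    max_iter: int = 5000
    se: str = "sandwich"  # "sandwich", "hessian", or "none"
    standardized: bool = True
    hessian_step: float = 1e-5  # central-difference step scale for the information matrix


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics of one FIML fit."""

    labels: list[str]
    theta: np.ndarray
    loglik: float
    n_free: int
    df: int
    converged: bool
    n_iterations: int
    gradient_norm: float
    n_persons: int
    implied_mean: np.ndarray
    implied_cov: np.ndarray
    se: np.ndarray | None = None
    vcov: np.ndarray | None = None
    standardized: pd.DataFrame | None = None
    ram: RAMMatrices | None = None
    data_hash: str | None = None
    message: str = ""

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.labels, self.theta))

    def parameter_table(self) -> pd.DataFrame:
        """Flat parameter table (label, estimate, SE, 95% CI, standardized)."""
        tab = pd.DataFrame({"label": self.labels, "estimate": self.theta})
        tab["family"] = [l.split("_", 1)[0] for l in self.labels]
        if self.se is not None:
            tab["se"] = self.se
            tab["ci_low"] = self.theta - 1.959963984540054 * self.se
            tab["ci_high"] = self.theta + 1.959963984540054 * self.se
        if self.standardized is not None:
            std = self.standardized.set_index("label")
            tab = tab.join(
                std[["std_estimate", "std_ci_low", "std_ci_high", "is_standardized"]],
                on="label",
            )
        return tab

    def to_dict(self) -> dict:
        out = {
            "loglik": float(self.loglik),
            "n_free": int(self.n_free),
            "df": int(self.df),
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "gradient_norm": float(self.gradient_norm),
            "n_persons": int(self.n_persons),
            "estimates": {l: float(v) for l, v in zip(self.labels, self.theta)},
        }
        if self.se is not None:
            out["se"] = {l: float(v) for l, v in zip(self.labels, self.se)}
        if self.standardized is not None:
            out["standardized"] = self.standardized.to_dict(orient="records")
        return out


_PENALTY = 1e10  # finite objective at inadmissible (non-PD) points


def _preconditioner(ram: RAMMatrices, data: PanelData) -> np.ndarray:
    """Per-parameter scale factors equalizing gradient magnitudes.

    Each variable is assigned its construct's pooled observed SD (latent
    residuals, intercepts and slopes inherit the construct scale through
    their unit loadings); a free S-cell parameter then scales like the
    product of its two variable SDs, a mean like one SD, a regression like
    the predictor/outcome SD ratio. Log-parameterized variances are
    already scale-free.
    """
    import re

    cols = [ram.names[i] for i in ram.obs_idx]
    con_sd: dict[str, float] = {}
    for col in cols:
        m = re.match(r"([A-Za-z_]+?)(\d+)$", col)
        if not m:
            continue
        con_sd.setdefault(m.group(1), 0.0)
    for c in con_sd:
        idx = [k for k, col in enumerate(cols) if re.match(rf"{re.escape(c)}\d+$", col)]
        v = np.nanmean([np.nanvar(data.values[:, k]) for k in idx])
        con_sd[c] = float(np.sqrt(v)) if v > 0 else 1.0

    def var_scale(name: str) -> float:
        m = re.match(r"(?:R_|RI_|S_)?([A-Za-z_]+?)\d+$", name)
        return con_sd.get(m.group(1), 1.0) if m else 1.0

    p = np.ones(ram.n_free)
    for j, lab in enumerate(ram.labels):
        if lab in ram.variance_labels:
            continue
        mat, i, k = ram.free[lab][0]
        si, sk = var_scale(ram.names[i]), var_scale(ram.names[k])
        if mat == "S":
            p[j] = si * sk
        elif mat == "M":
            p[j] = si
        else:  # A cell: coefficient of variable k predicting variable i
            p[j] = sk / si
    return np.maximum(p, 1e-8)


def _internal_transform(ram: RAMMatrices):
    """Masks and maps between natural and internal (log-variance) scale."""
    is_var = np.array([lab in ram.variance_labels for lab in ram.labels])

    def to_internal(theta):
        x = np.array(theta, dtype=float)
        x[is_var] = np.log(np.maximum(x[is_var], 1e-300))
        return x

    def to_natural(x):
        theta = np.array(x, dtype=float)
        theta[is_var] = np.exp(np.minimum(theta[is_var], 700.0))
        return theta

    return is_var, to_internal, to_natural


def fit(
    model: RAMMatrices | ModelSpec,
    data,
    start: np.ndarray | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Maximize the FIML log-likelihood by quasi-Newton iteration.

    Starts from the deterministic :func:`start_values` unless ``start`` is
    given. Optimizes the mean (per-person) negative log-likelihood with
    variances log-parameterized; convergence requires the projected
    gradient below ``options.gtol`` on that scale. A non-converged fit is
    returned flagged, never silently.
    """
    ram = compile_spec(model) if isinstance(model, ModelSpec) else model
    opts = options or FitOptions()
    data = _as_panel(data, ram)
    n = data.n_persons
    theta0 = np.asarray(start, dtype=float) if start is not None else start_values(ram, data)
    if theta0.shape != (ram.n_free,):
        raise ValueError(f"start must have length {ram.n_free}")
    is_var, to_internal, to_natural = _internal_transform(ram)
    pre = _preconditioner(ram, data)
    x0 = to_internal(theta0) / pre

    def objective(z):
        theta = to_natural(z * pre)
        ll, grad = _loglik_and_grad(ram, theta, data)
        if not np.isfinite(ll):
            return _PENALTY, np.zeros_like(z)
        g = grad.copy()
        g[is_var] *= theta[is_var]  # chain rule through log-parameterization
        return -ll / n, -(g * pre) / n

    # variances may legitimately sit on the zero boundary (e.g. a random
    # slope with no true variance); bound their logs below and judge
    # convergence by the projected gradient
    lower = np.full(ram.n_free, -np.inf)
    lower[is_var] = (np.log(np.maximum(theta0[is_var], 1e-300)) - 25.0) / pre[is_var]
    res, gnorm = _minimize_with_restarts(objective, x0, lower, opts)
    theta_hat = to_natural(res.x * pre)
    ll_hat, _ = _loglik_and_grad(ram, theta_hat, data)
    # converged: projected gradient small, or the optimizer exhausted the
    # objective's relative precision while the gradient is already modest
    # (plateau directions, e.g. covariances of a zero-variance slope)
    converged = bool(gnorm < 100 * opts.gtol or (res.success and gnorm < 1e-2))

    mu, Sigma = ram.implied_moments(theta_hat)
    p = len(mu)
    result = FitResult(
        labels=list(ram.labels),
        theta=theta_hat,
        loglik=float(ll_hat),
        n_free=ram.n_free,
        df=p * (p + 1) // 2 + p - ram.n_free,
        converged=converged,
        n_iterations=int(res.nit),
        gradient_norm=gnorm,
        n_persons=n,
        implied_mean=mu,
        implied_cov=Sigma,
        ram=ram,
        data_hash=data.content_hash(),
        message=str(res.message),
    )
    if opts.se in ("sandwich", "hessian") and converged:
        try:
            se, vcov = sandwich_se(
                ram, theta_hat, data, kind=opts.se, step=opts.hessian_step, return_vcov=True
            )
            result.se = se
            result.vcov = vcov
        except np.linalg.LinAlgError as e:
            result.message += f"; SE computation failed: {e}"
        if result.vcov is not None and opts.standardized:
            result.standardized = standardize(result)
    return result


# ---------------------------------------------------------------------------
# sandwich standard errors


def _observed_information(ram: RAMMatrices, theta: np.ndarray, data: PanelData, step: float):
    """Negative Hessian of the total log-likelihood by central differences
    of the analytic gradient."""
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        h = step * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        _, gp = _loglik_and_grad(ram, tp, data)
        _, gm = _loglik_and_grad(ram, tm, data)
        H[:, j] = (gp - gm) / (2.0 * h)
    H = -(H + H.T) / 2.0
    return H


def sandwich_se(
    ram: RAMMatrices,
    theta_hat: np.ndarray,
    data,
    kind: str = "sandwich",
    step: float = 1e-5,
    return_vcov: bool = False,
):
    """Huber-White robust standard errors H^-1 B H^-1 (or plain H^-1).

    H is the observed information; B the sum of per-person score outer
    products. Raises on singular information, naming the parameters
    aligned with its null space (an under-identification signal).
    """
    data = _as_panel(data, ram)
    if data.n_persons < 2:
        raise np.linalg.LinAlgError(
            "sandwich covariance requires at least 2 persons (score outer-product "
            "matrix is rank-deficient at n=1)"
        )
    H = _observed_information(ram, np.asarray(theta_hat, float), data, step)
    # test definiteness on the diagonally scaled matrix: raw curvatures span
    # many orders of magnitude across variance/mean/regression parameters
    dH = np.sqrt(np.maximum(np.abs(np.diag(H)), 1e-300))
    Hs = H / np.outer(dH, dH)
    w, V = np.linalg.eigh(Hs)
    if np.any(np.diag(H) <= 0) or np.any(w <= 1e-8):
        bad = np.where(w <= 1e-8)[0]
        offenders = set(np.array(ram.labels)[np.diag(H) <= 0])
        for b in bad:
            comp = np.abs(V[:, b])
            offenders.update(np.array(ram.labels)[comp > 0.3 * comp.max()])
        raise np.linalg.LinAlgError(
            f"observed information is singular; parameters possibly under-identified: "
            f"{sorted(offenders)}"
        )
    Hinv = (V @ np.diag(1.0 / w) @ V.T) / np.outer(dH, dH)
    if kind == "hessian":
        vcov = Hinv
    else:
        scores = _per_person_scores(ram, np.asarray(theta_hat, float), data)
        B = scores.T @ scores
        vcov = Hinv @ B @ Hinv
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    if return_vcov:
        return se, vcov
    return se


# ---------------------------------------------------------------------------
# standardized solution


def _standardized_vector(ram: RAMMatrices, theta: np.ndarray):
    """Standardized value per label, plus a flag for entries reported raw.

    Regressions are scaled by the model-implied (marginal) SDs of the
    predictor and outcome variables; covariances become correlations using
    the S-matrix variances of the two variables (innovation/marginal
    residual variances, intercept variances); variance parameters are left
    on the raw scale and flagged; means are left raw and flagged.
    """
    A, S, M = ram.realize(theta)
    k = A.shape[0]
    B = np.linalg.solve(np.eye(k) - A, np.eye(k))
    C = B @ S @ B.T
    vals = np.zeros(ram.n_free)
    is_std = np.zeros(ram.n_free, dtype=bool)
    for li, label in enumerate(ram.labels):
        mat, i, j = ram.free[label][0]
        kind = ram.cell_kind[(mat, i, j)]
        val = theta[li]
        if mat == "A" and kind == "regression":
            denom = np.sqrt(max(C[i, i], 1e-300))
            vals[li] = val * np.sqrt(max(C[j, j], 0.0)) / denom
            is_std[li] = True
        elif mat == "S" and i != j:
            denom = np.sqrt(max(S[i, i] * S[j, j], 1e-300))
            vals[li] = val / denom
            is_std[li] = True
        else:
            vals[li] = val  # variances and means reported unstandardized
    return vals, is_std


def standardize(result: FitResult) -> pd.DataFrame:
    """Standardized parameter table with delta-method 95% intervals.

    Covariances (within-wave residual, intercept, slope) are reported as
    correlations; regressions are scaled by model-implied predictor and
    outcome SDs; means and variances stay on the raw scale and are flagged
    ``is_standardized = False`` (mirroring the convention of reporting
    growth-factor means unstandardized).
    """
    if result.ram is None:
        raise ValueError("result lacks its RAM matrices")
    ram = result.ram
    theta = result.theta
    vals, is_std = _standardized_vector(ram, theta)
    se_std = np.full(ram.n_free, np.nan)
    if result.vcov is not None:
        J = np.zeros((ram.n_free, ram.n_free))
        for j in range(ram.n_free):
            h = 1e-6 * (1.0 + abs(theta[j]))
            tp = theta.copy()
            tp[j] += h
            tm = theta.copy()
            tm[j] -= h
            vp, _ = _standardized_vector(ram, tp)
            vm, _ = _standardized_vector(ram, tm)
            J[:, j] = (vp - vm) / (2.0 * h)
        var_std = np.einsum("ij,jk,ik->i", J, result.vcov, J)
        se_std = np.sqrt(np.maximum(var_std, 0.0))
    z = 1.959963984540054
    return pd.DataFrame(
        {
            "label": result.labels,
            "estimate": theta,
            "std_estimate": vals,
            "std_se": se_std,
            "std_ci_low": vals - z * se_std,
            "std_ci_high": vals + z * se_std,
            "is_standardized": is_std,
        }
    )


# ---------------------------------------------------------------------------
# saturated and baseline (independence) reference fits


@dataclass
class MomentFit:
    """Reference fit defined directly by moments (saturated / baseline)."""

    mean: np.ndarray
    cov: np.ndarray
    loglik: float
    n_free: int
    df: int
    n_persons: int
    converged: bool = True
    labels: list[str] = field(default_factory=list)
    data_hash: str | None = None


def _complete_ml_loglik(values: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    n, p = values.shape
    cf = cho_factor(Sigma, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    D = values - mu
    SiD = cho_solve(cf, D.T)
    quad = np.sum(D.T * SiD)
    return -0.5 * (n * (p * _LOG2PI + logdet) + quad)


def saturated_fit(data, max_iter: int = 500, tol: float = 1e-10) -> MomentFit:
    """ML fit of the unrestricted mean + covariance model.

    Complete data: closed form (sample mean, ML covariance). With
    missingness: EM for the multivariate normal, iterated to a relative
    log-likelihood change below ``tol``.
    """
    if not isinstance(data, PanelData):
        data = PanelData(data)
    V = data.values
    n, p = V.shape
    n_free = p + p * (p + 1) // 2
    mask = np.isnan(V)
    if not mask.any():
        mu = V.mean(axis=0)
        D = V - mu
        Sigma = D.T @ D / n
        ll = _complete_ml_loglik(V, mu, Sigma)
        return MomentFit(mu, Sigma, ll, n_free, 0, n, data_hash=data.content_hash())

    # EM start: available-case means/variances, zero covariances
    mu = np.nanmean(V, axis=0)
    var = np.nanvar(V, axis=0)
    Sigma = np.diag(np.maximum(var, 1e-8))
    ll_old = -np.inf
    patterns = data.patterns()
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        ll = 0.0
        for pat in patterns:
            o = pat["idx"]
            m = np.setdiff1d(np.arange(p), o)
            Y = pat["Y"]
            So = Sigma[np.ix_(o, o)]
            cf = cho_factor(So, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            R = Y - mu[o]
            SiR = cho_solve(cf, R.T).T
            ll += -0.5 * (
                pat["n"] * (len(o) * _LOG2PI + logdet) + np.sum(R * SiR)
            )
            Xfull = np.zeros((pat["n"], p))
            Xfull[:, o] = Y
            Cadd = np.zeros((p, p))
            if m.size:
                Smo = Sigma[np.ix_(m, o)]
                cond_mean = mu[m] + (Smo @ cho_solve(cf, R.T)).T
                Xfull[:, m] = cond_mean
                Cadd_mm = Sigma[np.ix_(m, m)] - Smo @ cho_solve(cf, Smo.T)
                Cadd[np.ix_(m, m)] = pat["n"] * Cadd_mm
            T1 += Xfull.sum(axis=0)
            T2 += Xfull.T @ Xfull + Cadd
        mu = T1 / n
        Sigma = T2 / n - np.outer(mu, mu)
        Sigma = (Sigma + Sigma.T) / 2.0
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            break
        ll_old = ll
    # final log-likelihood at converged moments
    llf = 0.0
    for pat in patterns:
        o = pat["idx"]
        So = Sigma[np.ix_(o, o)]
        cf = cho_factor(So, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        R = pat["Y"] - mu[o]
        SiR = cho_solve(cf, R.T).T
        llf += -0.5 * (pat["n"] * (len(o) * _LOG2PI + logdet) + np.sum(R * SiR))
    return MomentFit(mu, Sigma, llf, n_free, 0, n, data_hash=data.content_hash())


def baseline_fit(data) -> MomentFit:
    """Independence model: free means and variances, all covariances zero.

    Factorizes over variables, so the FIML solution is available in closed
    form per column (observed-case mean and ML variance).
    """
    if not isinstance(data, PanelData):
        data = PanelData(data)
    V = data.values
    n, p = V.shape
    mu = np.nanmean(V, axis=0)
    var = np.nanvar(V, axis=0)
    ll = 0.0
    for j in range(p):
        y = V[:, j]
        y = y[~np.isnan(y)]
        ll += -0.5 * (len(y) * (_LOG2PI + np.log(var[j])) + ((y - mu[j]) ** 2).sum() / var[j])
    n_free = 2 * p
    df = p + p * (p + 1) // 2 - n_free
    return MomentFit(mu, np.diag(var), ll, n_free, df, n, data_hash=data.content_hash())


# ---------------------------------------------------------------------------
# multiple-group fitting


@dataclass
class MultiGroupFitResult:
    """Joint fit over groups; per-group estimates share any equal labels."""

    groups: list[str]
    labels: list[str]  # joint free-parameter labels
    theta: np.ndarray
    loglik: float
    n_free: int
    df: int
    converged: bool
    gradient_norm: float
    group_results: dict[str, FitResult]

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "loglik": float(self.loglik),
            "n_free": int(self.n_free),
            "df": int(self.df),
            "converged": bool(self.converged),
            "estimates": {l: float(v) for l, v in zip(self.labels, self.theta)},
        }


def fit_multigroup(
    specs: dict[str, ModelSpec],
    data_by_group: dict[str, "PanelData | pd.DataFrame"],
    options: FitOptions | None = None,
) -> MultiGroupFitResult:
    """Fit per-group specs jointly, honoring cross-group shared labels.

    Labels appearing in several group specs (equality constraints from
    :func:`~lcmsr.model_spec.split_groups`) are estimated once; all other
    parameters are group-specific. With no shared labels this coincides
    with fitting each group separately.
    """
    opts = options or FitOptions()
    groups = list(specs)
    if set(groups) - set(data_by_group):
        raise ValueError("missing data for group(s) " f"{sorted(set(groups) - set(data_by_group))}")
    rams = {g: compile_spec(specs[g]) for g in groups}
    datas = {g: _as_panel(data_by_group[g], rams[g]) for g in groups}

    label_lists = [rams[g].labels for g in groups]
    n_unique = len(set().union(*map(set, label_lists)))
    if n_unique == sum(len(ls) for ls in label_lists):
        # no cross-group equality constraints: groups are independent and
        # the joint ML factorizes into separate fits
        group_results = {
            g: fit(rams[g], datas[g], options=opts) for g in groups
        }
        joint_labels = [lab for g in groups for lab in rams[g].labels]
        theta = np.concatenate([group_results[g].theta for g in groups])
        return MultiGroupFitResult(
            groups=groups,
            labels=joint_labels,
            theta=theta,
            loglik=float(sum(r.loglik for r in group_results.values())),
            n_free=n_unique,
            df=sum(r.df for r in group_results.values()),
            converged=all(r.converged for r in group_results.values()),
            gradient_norm=max(r.gradient_norm for r in group_results.values()),
            group_results=group_results,
        )

    joint_labels: list[str] = []
    joint_index: dict[str, int] = {}
    for g in groups:
        for lab in rams[g].labels:
            if lab not in joint_index:
                joint_index[lab] = len(joint_labels)
                joint_labels.append(lab)
    maps = {
        g: np.array([joint_index[lab] for lab in rams[g].labels], dtype=int) for g in groups
    }
    k = len(joint_labels)
    variance_labels = set()
    for g in groups:
        variance_labels |= rams[g].variance_labels
    is_var = np.array([lab in variance_labels for lab in joint_labels])

    theta0 = np.zeros(k)
    counts = np.zeros(k)
    pre = np.zeros(k)
    for g in groups:
        sv = start_values(rams[g], datas[g])
        np.add.at(theta0, maps[g], sv)
        np.add.at(pre, maps[g], _preconditioner(rams[g], datas[g]))
        np.add.at(counts, maps[g], 1.0)
    theta0 /= np.maximum(counts, 1.0)
    pre /= np.maximum(counts, 1.0)
    pre = np.maximum(pre, 1e-8)

    n_total = sum(datas[g].n_persons for g in groups)

    def objective(z):
        theta = z * pre
        theta[is_var] = np.exp(np.minimum(theta[is_var], 700.0))
        ll_total = 0.0
        grad = np.zeros(k)
        for g in groups:
            ll, gr = _loglik_and_grad(rams[g], theta[maps[g]], datas[g])
            if not np.isfinite(ll):
                return _PENALTY, np.zeros(k)
            ll_total += ll
            np.add.at(grad, maps[g], gr)
        grad[is_var] *= theta[is_var]
        return -ll_total / n_total, -(grad * pre) / n_total

    x0 = theta0.copy()
    x0[is_var] = np.log(np.maximum(x0[is_var], 1e-300))
    x0 = x0 / pre
    lower = np.full(k, -np.inf)
    lower[is_var] = x0[is_var] - 25.0 / pre[is_var]
    res, gnorm = _minimize_with_restarts(objective, x0, lower, opts)
    theta_hat = res.x * pre
    theta_hat[is_var] = np.exp(np.minimum(theta_hat[is_var], 700.0))
    converged = bool(gnorm < 100 * opts.gtol or (res.success and gnorm < 1e-2))

    group_results = {}
    total_moments = 0
    for gname in groups:
        ram = rams[gname]
        th = theta_hat[maps[gname]]
        mu, Sigma = ram.implied_moments(th)
        p = len(mu)
        total_moments += p * (p + 1) // 2 + p
        ll_g, grad_g = _loglik_and_grad(ram, th, datas[gname])
        fr = FitResult(
            labels=list(ram.labels),
            theta=th,
            loglik=float(ll_g),
            n_free=ram.n_free,
            df=p * (p + 1) // 2 + p - ram.n_free,
            converged=converged,
            n_iterations=int(res.nit),
            gradient_norm=gnorm,
            n_persons=datas[gname].n_persons,
            implied_mean=mu,
            implied_cov=Sigma,
            ram=ram,
            data_hash=datas[gname].content_hash(),
        )
        if opts.se in ("sandwich", "hessian") and converged:
            try:
                se, vcov = sandwich_se(
                    ram, th, datas[gname], kind=opts.se, step=opts.hessian_step, return_vcov=True
                )
                fr.se = se
                fr.vcov = vcov
                if opts.standardized:
                    fr.standardized = standardize(fr)
            except np.linalg.LinAlgError as e:
                fr.message = f"SE computation failed: {e}"
        group_results[gname] = fr

    ll_total = sum(group_results[g].loglik for g in groups)
    return MultiGroupFitResult(
        groups=groups,
        labels=joint_labels,
        theta=theta_hat,
        loglik=float(ll_total),
        n_free=k,
        df=total_moments - k,
        converged=converged,
        gradient_norm=gnorm,
        group_results=group_results,
    )
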