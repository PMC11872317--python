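"""scikit-learn style estimator facade over the FIML machinery."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .estimation import FitOptions, PanelData, fit
from .model_spec import ModelSpec, canonical_bivariate, compile_spec

__all__ = ["LCMSR"]


class LCMSR(BaseEstimator):
    """Latent curve model with structured residuals, fit by FIML.

    Parameters
    ----------
    spec:
        A :class:`~lcmsr.model_spec.ModelSpec`. ``None`` selects the
        canonical bivariate structure (FI random intercepts + LS random
        intercepts with fixed slopes over two bursts of 7 waves).
    se:
        ``"sandwich"`` (Huber-White, default), ``"hessian"`` or ``"none"``.
    gtol, ftol, max_iter:
        Convergence controls of the quasi-Newton optimization (tolerances
        apply to the mean per-person log-likelihood).
    standardized:
        Whether to compute the standardized solution after fitting.

    Attributes (after ``fit``)
    --------------------------
    params_ : dict label -> estimate (natural scale)
    se_ : dict label -> sandwich standard error
    loglik_ : float
    df_ : int
    n_free_ : int
    converged_ : bool
    implied_mean_, implied_cov_ : model-implied observed moments
    standardized_ : DataFrame with the standardized solution
    result_ : the underlying :class:`~lcmsr.estimation.FitResult`
    """

    def __init__(
        self,
        spec: ModelSpec | None = None,
        se: str = "sandwich",
        gtol: float = 1e-5,
        ftol: float = 1e-11,
        max_iter: int = 5000,
        standardized: bool = True,
    ):
        self.spec = spec
        self.se = se
        self.gtol = gtol
        self.ftol = ftol
        self.max_iter = max_iter
        self.standardized = standardized

    def fit(self, X, y=None):
        """Fit the model to a wide person x variable table.

        ``X`` may be a DataFrame whose columns include the spec's observed
        variables, a :class:`PanelData`, or an array in spec column order.
        """
        spec = self.spec if self.spec is not None else canonical_bivariate()
        ram = compile_spec(spec)
        if isinstance(X, np.ndarray):
            X = PanelData(X, columns=[ram.names[i] for i in ram.obs_idx])
        opts = FitOptions(
            gtol=self.gtol,
            ftol=self.ftol,
            max_iter=self.max_iter,
            se=self.se if self.se in ("sandwich", "hessian") else "none",
            standardized=self.standardized,
        )
        res = fit(ram, X, options=opts)
        self.spec_ = spec
        self.result_ = res
        self.params_ = res.estimates
        self.se_ = dict(zip(res.labels, res.se)) if res.se is not None else None
        self.loglik_ = res.loglik
        self.df_ = res.df
        self.n_free_ = res.n_free
        self.converged_ = res.converged
        self.n_iter_ = res.n_iterations
        self.implied_mean_ = res.implied_mean
        self.implied_cov_ = res.implied_cov
        self.standardized_ = res.standardized
        return self

    def score(self, X, y=None) -> float:
        """Mean per-person log-likelihood of ``X`` under the fitted model."""
        from .estimation import fiml_loglik

        if not hasattr(self, "result_"):
            raise AttributeError("LCMSR is not fitted")
        ram = self.result_.ram
        if isinstance(X, np.ndarray):
            X = PanelData(X, columns=[ram.names[i] for i in ram.obs_idx])
        if not isinstance(X, PanelData):
            X = PanelData(X)
        ll = fiml_loglik(ram, self.result_.theta, X)
        return float(ll / X.n_persons)

    def parameter_table(self) -> pd.DataFrame:
        if not hasattr(self, "result_"):
            raise AttributeError("LCMSR is not fitted")
        return self.result_.parameter_table()
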