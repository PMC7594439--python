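"""One-latent-factor path model fitted by maximum likelihood.

Six observed indicators load on a single latent strain factor, which in
turn carries one structural path to the outcome (tympanic temperature).
Algebraically this is a one-factor model on p = 7 variables whose seventh
loading is the structural path; the model-implied covariance is

    Sigma(theta) = lambda lambda' + Psi

with Psi diagonal apart from any declared indicator error covariances.
Identification fixes the latent variance at 1 with all loadings free.
The ML discrepancy  F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p  is
minimized by quasi-Newton iteration with an analytic gradient; the test
statistic is chi^2 = (n - 1) F(theta-hat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InputError, NumericalError

DEFAULT_INDICATORS = ("t_dry", "t_wet", "t_globe", "v_air", "metabolism", "clo")
DEFAULT_OUTCOME = "tympanic"

_GRAD_TOL = 1e-8
_MAX_ITER = 500
_MIN_ERR_VAR = 1e-6


@dataclass(frozen=True)
class PathModelSpec:
    """Declares the indicators, the outcome and optional error covariances."""

    indicators: tuple[str, ...] = DEFAULT_INDICATORS
    outcome: str = DEFAULT_OUTCOME
    latent: str = "heat_strain"
    error_covariances: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.outcome in self.indicators:
            raise InputError(f"outcome {self.outcome!r} must not be an indicator")
        if len(set(self.indicators)) != len(self.indicators):
            raise InputError("duplicate indicator names")
        for a, b in self.error_covariances:
            if a not in self.indicators or b not in self.indicators:
                raise InputError(
                    f"error covariance ({a}, {b}) references undeclared indicators"
                )
            if a == b:
                raise InputError(f"error covariance pair ({a}, {b}) must be distinct")

    @property
    def names(self) -> tuple[str, ...]:
        return self.indicators + (self.outcome,)

    @property
    def n_free(self) -> int:
        p = len(self.names)
        return 2 * p + len(self.error_covariances)

    def df(self) -> int:
        p = len(self.names)
        return p * (p + 1) // 2 - self.n_free


@dataclass
class PathModelFit:
    """Converged (or flagged) ML solution in standardized form."""

    spec: PathModelSpec
    loadings: dict[str, float]          # standardized indicator loadings
    gamma: float                        # standardized structural path to outcome
    error_variances: dict[str, float]   # standardized residual variances
    error_covariances: dict[tuple[str, str], float]
    n: int
    chi2: float
    df: int
    discrepancy: float
    converged: bool
    implied: pd.DataFrame = field(repr=False)   # model-implied covariance
    sample: pd.DataFrame = field(repr=False)    # analyzed covariance

    @property
    def heywood(self) -> bool:
        """Any negative standardized residual variance (improper solution)."""
        return any(v < 0 for v in self.error_variances.values())


@dataclass(frozen=True)
class FitIndices:
    gfi: float
    agfi: float
    nfi: float
    cfi: float
    ifi: float
    rmsea: float
    normed_chi2: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "GFI": self.gfi, "AGFI": self.agfi, "NFI": self.nfi, "CFI": self.cfi,
            "IFI": self.ifi, "RMSEA": self.rmsea, "normed_chi2": self.normed_chi2,
            "chi2_p_value": self.p_value,
        }


def corr_to_cov(corr: np.ndarray, sds: Sequence[float]) -> np.ndarray:
    """Rescale a correlation matrix to a covariance matrix."""
    d = np.asarray(sds, dtype=float)
    if (d <= 0).any():
        raise InputError(f"standard deviations must be positive: {d}")
    return np.asarray(corr, dtype=float) * np.outer(d, d)


def _as_matrix(S, names: Sequence[str]) -> np.ndarray:
    """Coerce input (DataFrame with labels, or array) into model order."""
    if isinstance(S, pd.DataFrame):
        missing = [v for v in names if v not in S.columns]
        if missing:
            raise InputError(f"covariance input lacks variable(s): {missing}")
        S = S.loc[list(names), list(names)].to_numpy(dtype=float)
    else:
        S = np.asarray(S, dtype=float)
    p = len(names)
    if S.shape != (p, p):
        raise InputError(f"expected a {p}x{p} matrix, got {S.shape}")
    if not np.allclose(S, S.T, atol=1e-10):
        raise InputError("covariance matrix is not symmetric")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise NumericalError("covariance matrix is not positive definite")
    return S


def _implied(lam: np.ndarray, psi: np.ndarray, pairs: np.ndarray, phi: np.ndarray) -> np.ndarray:
    sigma = np.outer(lam, lam) + np.diag(psi)
    for (i, j), v in zip(pairs, phi):
        sigma[i, j] += v
        sigma[j, i] += v
    return sigma


def fit_ml(S, n: int, spec: PathModelSpec | None = None) -> PathModelFit:
    """Fit the model to a sample covariance (or correlation) matrix.

    ``S`` is a labeled :class:`pandas.DataFrame` or an array ordered as
    ``spec.indicators + (outcome,)``.  Raises on non-PD input; a fit that
    exhausts the iteration budget is returned with ``converged=False``.
    """
    spec = spec or PathModelSpec()
    names = spec.names
    p = len(names)
    if n <= p:
        raise InputError(f"sample size n={n} must exceed the number of variables p={p}")
    S_raw = _as_matrix(S, names)
    # the model family is closed under diagonal rescaling, so optimize on the
    # correlation scale (well-conditioned) and rescale the solution afterwards
    d_raw = np.sqrt(np.diag(S_raw))
    S_mat = S_raw / np.outer(d_raw, d_raw)
    pairs = np.array(
        [(names.index(a), names.index(b)) for a, b in spec.error_covariances], dtype=int
    ).reshape(-1, 2)
    k = len(pairs)

    sign_logdet_S, logdet_S = np.linalg.slogdet(S_mat)
    diag_S = np.diag(S_mat)

    def unpack(theta):
        return theta[:p], theta[p:2 * p], theta[2 * p:]

    def objective(theta):
        lam, psi, phi = unpack(theta)
        sigma = _implied(lam, psi, pairs, phi)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e12, np.zeros_like(theta)
        sigma_inv = np.linalg.inv(sigma)
        f = logdet + np.trace(S_mat @ sigma_inv) - logdet_S - p
        # dF = tr(G dSigma) with G = Sigma^-1 (Sigma - S) Sigma^-1
        G = sigma_inv @ (sigma - S_mat) @ sigma_inv
        g_lam = 2.0 * G @ lam
        g_psi = np.diag(G).copy()
        g_phi = np.array([2.0 * G[i, j] for i, j in pairs])
        return f, np.concatenate([g_lam, g_psi, g_phi])

    theta0 = np.concatenate([
        0.7 * np.sqrt(diag_S),       # loadings start
        0.5 * diag_S,                # error variances start
        np.zeros(k),
    ])
    bounds = [(None, None)] * p + [(_MIN_ERR_VAR, None)] * p + [(None, None)] * k
    res = optimize.minimize(
        objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": _MAX_ITER, "gtol": _GRAD_TOL, "ftol": 1e-14},
    )
    lam, psi, phi = unpack(res.x)
    sigma = _implied(lam, psi, pairs, phi)
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) <= 1e-6
    if not converged:
        warnings.warn(f"ML fit did not converge: {res.message}", RuntimeWarning, stacklevel=2)

    # standardize on the model-implied variances; fix the sign so the
    # outcome path (and hence the dominant loading block) is positive
    scale = np.sqrt(np.diag(sigma))
    lam_std = lam / scale
    if lam_std.sum() < 0:
        lam_std = -lam_std
    psi_std = psi / scale**2
    cov_std = {
        (names[i], names[j]): phi_v / (scale[i] * scale[j])
        for (i, j), phi_v in zip(pairs, phi)
    }

    f_min = max(float(res.fun), 0.0)
    sigma_raw = sigma * np.outer(d_raw, d_raw)  # back to the input scale
    labeled = pd.DataFrame(sigma_raw, index=list(names), columns=list(names))
    return PathModelFit(
        spec=spec,
        loadings={name: float(l) for name, l in zip(names[:-1], lam_std[:-1])},
        gamma=float(lam_std[-1]),
        error_variances={name: float(v) for name, v in zip(names, psi_std)},
        error_covariances=cov_std,
        n=int(n),
        chi2=(n - 1) * f_min,
        df=spec.df(),
        discrepancy=f_min,
        converged=converged,
        implied=labeled,
        sample=pd.DataFrame(S_raw, index=list(names), columns=list(names)),
    )


def effects(fit: PathModelFit) -> pd.DataFrame:
    """Standardized direct and indirect effects of each indicator on the outcome.

    Direct effect = the indicator's loading on the latent factor;
    indirect effect on the outcome = loading x structural path.
    """
    if not fit.converged:
        raise NumericalError("effects require a converged fit")
    rows = [
        {"variable": name, "direct": lam, "indirect": lam * fit.gamma}
        for name, lam in fit.loadings.items()
    ]
    return pd.DataFrame(rows).set_index("variable")


def independence_null(S, n: int, names: Sequence[str] | None = None) -> PathModelFit:
    """Baseline model with all covariances fixed to zero (diagonal Sigma).

    Its chi^2 equals -(n-1) ln|R| with R the correlation matrix;
    df0 = p(p-1)/2.
    """
    if isinstance(S, pd.DataFrame):
        names = tuple(S.columns)
    elif names is None:
        S = np.asarray(S, dtype=float)
        names = tuple(f"x{i}" for i in range(S.shape[0]))
    spec = PathModelSpec(indicators=tuple(names[:-1]), outcome=names[-1])
    S_mat = _as_matrix(S, names)
    p = len(names)
    d = np.sqrt(np.diag(S_mat))
    R = S_mat / np.outer(d, d)
    sign, logdet_R = np.linalg.slogdet(R)
    if sign <= 0:
        raise NumericalError("correlation matrix is singular")
    f0 = -logdet_R
    sigma0 = np.diag(np.diag(S_mat))
    labeled = pd.DataFrame(sigma0, index=list(names), columns=list(names))
    return PathModelFit(
        spec=spec,
        loadings={name: 0.0 for name in names[:-1]},
        gamma=0.0,
        error_variances={name: 1.0 for name in names},
        error_covariances={},
        n=int(n),
        chi2=(n - 1) * f0,
        df=p * (p - 1) // 2,
        discrepancy=f0,
        converged=True,
        implied=labeled,
        sample=pd.DataFrame(S_mat, index=list(names), columns=list(names)),
    )


def fit_indices(fit: PathModelFit, null_fit: PathModelFit | None = None) -> FitIndices:
    """Absolute, comparative and parsimony fit summaries of a converged fit."""
    if null_fit is None:
        null_fit = independence_null(fit.sample, fit.n)
    S = fit.sample.to_numpy()
    sigma = fit.implied.to_numpy()
    p = S.shape[0]
    chi2, df, n = fit.chi2, fit.df, fit.n
    chi2_0, df_0 = null_fit.chi2, null_fit.df

    sigma_inv_S = np.linalg.solve(sigma, S)
    resid = sigma_inv_S - np.eye(p)
    gfi = 1.0 - np.trace(resid @ resid) / np.trace(sigma_inv_S @ sigma_inv_S)
    nfi = (chi2_0 - chi2) / chi2_0 if chi2_0 > 0 else 1.0
    denom = max(chi2_0 - df_0, chi2 - df, 0.0)
    cfi = 1.0 - (max(chi2 - df, 0.0) / denom if denom > 0 else 0.0)
    ifi = (chi2_0 - chi2) / (chi2_0 - df) if chi2_0 != df else np.nan

    if df > 0:
        agfi = 1.0 - (p * (p + 1)) / (2.0 * df) * (1.0 - gfi)
        rmsea = np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
        normed = chi2 / df
        p_value = float(stats.chi2.sf(chi2, df))
    else:
        warnings.warn("df = 0: RMSEA and normed chi^2 are undefined", RuntimeWarning,
                      stacklevel=2)
        agfi, rmsea, normed, p_value = np.nan, np.nan, np.nan, np.nan

    return FitIndices(
        gfi=float(gfi), agfi=float(agfi), nfi=float(nfi), cfi=float(cfi),
        ifi=float(ifi), rmsea=float(rmsea), normed_chi2=float(normed),
        p_value=p_value,
    )
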