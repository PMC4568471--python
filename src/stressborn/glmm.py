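"""Random-intercept generalised linear mixed models fitted by maximum likelihood.

This module is the statistical engine behind every analysis stage: binomial
(logit), Poisson (log) and Gaussian (identity) models with up to two crossed
random intercepts (individual identity and region in the reproductive-history
models; female identity in the hormone models).

Fitting strategy
----------------
* Non-Gaussian families: the marginal likelihood integrates the conditional
  likelihood over the Gaussian random intercepts.  We maximise a Laplace
  approximation of that integral jointly over the fixed effects and the
  log-standard-deviations of the random intercepts, with the random-effect
  mode found by an inner Newton iteration.  The two-factor structure
  (one diagonal block per factor plus a sparse cross block) is solved by
  Schur elimination of the larger factor, so each inner step costs O(n).
* Gaussian family: the marginal likelihood is available in closed form
  (a multivariate normal); we maximise it exactly (ML, not REML) with the
  fixed effects profiled out by generalised least squares.

``brute_force_loglik`` provides an independent slow oracle: dense numerical
integration over the random effects, feasible only on tiny instances, used to
validate the Laplace approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "GlmmError",
    "ConvergenceError",
    "fit_glmm",
    "laplace_loglik",
    "brute_force_loglik",
    "likelihood_ratio_test",
    "marginal_predict",
    "wald_test",
]

_SD_LOWER = 1e-4          # optimizer bound on a random-effect SD (logit/log scale)
_SD_UPPER = 25.0
_BOUNDARY_SD = 1e-3       # below this a variance component is reported as boundary


class GlmmError(ValueError):
    """Structured model-specification or data error."""


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails after all restarts; carries the trace."""

    def __init__(self, message: str, trace: Optional[list] = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    Parameters
    ----------
    formula:
        patsy formula with the response on the left-hand side, e.g.
        ``"reproduced ~ high_stress_born * age_c + censored + C(birth_decade)"``.
    groups:
        names of up to two categorical columns each contributing a random
        intercept (e.g. ``("id", "region")``).  May be empty.
    family:
        one of ``"binomial"`` (logit link), ``"poisson"`` (log link),
        ``"gaussian"`` (identity link).
    offset:
        optional column name added to the linear predictor with coefficient 1.
    """

    formula: str
    groups: tuple = ()
    family: str = "binomial"
    offset: Optional[str] = None

    def __post_init__(self):
        if self.family not in ("binomial", "poisson", "gaussian"):
            raise GlmmError(f"unknown family {self.family!r}")
        if len(self.groups) > 2:
            raise GlmmError("at most two random-intercept factors are supported")


@dataclass
class FitResult:
    """Fitted mixed model: coefficient table, variance components, likelihood."""

    spec: ModelSpec
    params: np.ndarray                 # fixed-effect estimates
    param_names: list
    se: np.ndarray
    vcomp: dict                        # factor name -> variance (sigma^2)
    scale: Optional[float]             # residual variance (Gaussian only)
    loglik: float
    n_obs: int
    n_groups: dict                     # factor name -> number of levels
    converged: bool
    boundary: dict                     # factor name -> True if variance at 0 boundary
    design_info: object = field(repr=False, default=None)
    group_levels: dict = field(repr=False, default_factory=dict)
    dropped_columns: list = field(default_factory=list)
    cov_params: Optional[np.ndarray] = field(repr=False, default=None)

    @property
    def k_params(self) -> int:
        k = len(self.params) + len(self.vcomp)
        if self.scale is not None:
            k += 1
        return k

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k_params

    @property
    def z_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z_values))

    def coef(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.param_names,
                "estimate": self.params,
                "std_error": self.se,
                "z_value": self.z_values,
                "p_value": self.p_values,
            }
        )

    def to_dict(self) -> dict:
        """Serialisable summary mirroring a standard mixed-model output table."""
        return {
            "family": self.spec.family,
            "formula": self.spec.formula,
            "coefficients": [
                {
                    "term": t,
                    "estimate": float(b),
                    "std_error": float(s),
                    "z_value": float(z),
                    "p_value": float(p),
                }
                for t, b, s, z, p in zip(
                    self.param_names, self.params, self.se, self.z_values, self.p_values
                )
            ],
            "random_effects": {
                f: {"variance": float(v), "std_dev": float(np.sqrt(v))}
                for f, v in self.vcomp.items()
            },
            "scale": None if self.scale is None else float(self.scale),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "k_params": int(self.k_params),
            "n_obs": int(self.n_obs),
            "n_groups": {k: int(v) for k, v in self.n_groups.items()},
            "converged": bool(self.converged),
            "boundary": {k: bool(v) for k, v in self.boundary.items()},
        }


@dataclass
class LRTResult:
    chi_square: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "chi_square": float(self.chi_square),
            "df": int(self.df),
            "p_value": float(self.p_value),
        }


# ---------------------------------------------------------------------------
# families (canonical links, so the IRLS/Newton weight equals Var(mu))
# ---------------------------------------------------------------------------

def _binom_loglik(y, eta):
    # y*eta - log(1+exp(eta)), stable via softplus
    return y * eta - np.logaddexp(0.0, eta)


_ETA_MAX = 30.0  # exp(30) ~ 1e13: clip the Poisson predictor against overflow


def _pois_loglik(y, eta):
    return y * eta - np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX)) - special.gammaln(y + 1.0)


def _pois_mean(eta):
    return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))


def _family_funcs(family):
    if family == "binomial":
        return _binom_loglik, special.expit, lambda mu: mu * (1.0 - mu)
    if family == "poisson":
        return _pois_loglik, _pois_mean, lambda mu: mu
    raise GlmmError(f"no Laplace path for family {family!r}")


def _weight_prime(family, mu):
    """d W / d eta for the canonical link."""
    if family == "binomial":
        return mu * (1.0 - mu) * (1.0 - 2.0 * mu)
    if family == "poisson":
        return mu
    raise GlmmError(family)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _independent_columns(X: np.ndarray) -> list:
    """First-come maximal set of linearly independent columns."""
    keep: list = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    return keep


class _Design:
    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        if len(data) == 0:
            raise GlmmError("empty data")
        y_mat, X_mat = patsy.dmatrices(spec.formula, data, return_type="dataframe")
        self.y = np.asarray(y_mat.iloc[:, 0], dtype=float)
        X = np.asarray(X_mat, dtype=float)
        names = list(X_mat.columns)
        keep = _independent_columns(X)
        self.dropped = [names[j] for j in range(len(names)) if j not in keep]
        if self.dropped:
            warnings.warn(f"dropping aliased fixed-effect columns: {self.dropped}")
        self.X = X[:, keep]
        self.names = [names[j] for j in keep]
        self.design_info = X_mat.design_info
        self.n, self.p = self.X.shape
        # patsy drops rows with NA; require the caller to have handled missingness
        if len(self.y) != len(data):
            raise GlmmError(
                "rows with missing values in model variables; drop them explicitly"
            )
        self.offset = (
            np.asarray(data[spec.offset], dtype=float)
            if spec.offset is not None
            else np.zeros(self.n)
        )
        self.factors: list = []       # (name, codes, n_levels, levels)
        self.group_levels: dict = {}
        for g in spec.groups:
            codes, levels = pd.factorize(data[g], sort=True)
            if (codes < 0).any():
                raise GlmmError(f"missing values in grouping factor {g!r}")
            self.factors.append((g, codes.astype(np.int64), len(levels)))
            self.group_levels[g] = list(levels)
        # put the larger factor first so Schur elimination removes the big block
        self.factors.sort(key=lambda t: -t[2])


# ---------------------------------------------------------------------------
# structured linear algebra for H = Z'WZ + D^{-1}
# ---------------------------------------------------------------------------

class _HSolver:
    """Factorisation of H for 0, 1 or 2 random-intercept factors."""

    def __init__(self, design: _Design, W: np.ndarray, inv_var: Sequence[float]):
        self.design = design
        f = design.factors
        self.nf = len(f)
        if self.nf >= 1:
            c1, q1 = f[0][1], f[0][2]
            self.A = np.bincount(c1, weights=W, minlength=q1) + inv_var[0]
        if self.nf == 2:
            c1, q1 = f[0][1], f[0][2]
            c2, q2 = f[1][1], f[1][2]
            Cd = np.bincount(c2, weights=W, minlength=q2) + inv_var[1]
            B = np.bincount(c1 * q2 + c2, weights=W, minlength=q1 * q2).reshape(q1, q2)
            S = np.diag(Cd) - B.T @ (B / self.A[:, None])
            self.B = B
            self.S_chol = np.linalg.cholesky(S)
            self._logdet_S = 2.0 * np.sum(np.log(np.diag(self.S_chol)))

    def solve(self, g: list) -> list:
        """Solve H x = g where g is a list of per-factor vectors."""
        if self.nf == 0:
            return []
        if self.nf == 1:
            return [g[0] / self.A]
        t1 = g[0] / self.A
        rhs2 = g[1] - self.B.T @ t1
        x2 = _chol_solve(self.S_chol, rhs2)
        x1 = (g[0] - self.B @ x2) / self.A
        return [x1, x2]

    def logdet(self) -> float:
        if self.nf == 0:
            return 0.0
        ld = float(np.sum(np.log(self.A)))
        if self.nf == 2:
            ld += self._logdet_S
        return ld

    def _two_factor_pieces(self):
        if not hasattr(self, "_pieces"):
            q2 = self.S_chol.shape[0]
            Sinv = _chol_solve(self.S_chol, np.eye(q2))
            P = self.B / self.A[:, None]
            PS = P @ Sinv
            d1 = 1.0 / self.A + np.einsum("ij,ij->i", PS, P)
            self._pieces = (Sinv, PS, d1)
        return self._pieces

    def zhz_diag(self) -> np.ndarray:
        """Per-row diagonal of Z H^{-1} Z'."""
        f = self.design.factors
        if self.nf == 0:
            return np.zeros(self.design.n)
        c1 = f[0][1]
        if self.nf == 1:
            return 1.0 / self.A[c1]
        c2 = f[1][1]
        Sinv, PS, d1 = self._two_factor_pieces()
        return d1[c1] - 2.0 * PS[c1, c2] + np.diag(Sinv)[c2]

    def inv_trace_blocks(self) -> list:
        """Trace of H^{-1} restricted to each factor's diagonal block."""
        if self.nf == 0:
            return []
        if self.nf == 1:
            return [float(np.sum(1.0 / self.A))]
        Sinv, PS, d1 = self._two_factor_pieces()
        return [float(np.sum(d1)), float(np.trace(Sinv))]


def _chol_solve(L, b):
    y = np.linalg.solve(L, b)
    return np.linalg.solve(L.T, y)


# ---------------------------------------------------------------------------
# Laplace objective (non-Gaussian)
# ---------------------------------------------------------------------------

class _LaplaceObjective:
    def __init__(self, design: _Design, family: str):
        self.d = design
        self.family = family
        self.loglik, self.linkinv, self.varfun = _family_funcs(family)
        self.u_warm = [np.zeros(f[2]) for f in design.factors]

    def _eta(self, beta, u):
        eta = self.d.X @ beta + self.d.offset
        for (name, codes, q), uf in zip(self.d.factors, u):
            eta = eta + uf[codes]
        return eta

    def inner_mode(self, beta, inv_var, max_iter=100, tol=1e-10):
        """Newton iteration for the conditional mode of the random effects."""
        d = self.d
        u = [uf.copy() for uf in self.u_warm]
        eta = self._eta(beta, u)
        mu = self.linkinv(eta)
        pll = float(np.sum(self.loglik(d.y, eta))) - 0.5 * sum(
            iv * float(uf @ uf) for iv, uf in zip(inv_var, u)
        )
        for _ in range(max_iter):
            resid = d.y - mu
            g = [
                np.bincount(codes, weights=resid, minlength=q) - iv * uf
                for (name, codes, q), uf, iv in zip(d.factors, u, inv_var)
            ]
            gnorm = max((float(np.max(np.abs(gf))) for gf in g), default=0.0)
            W = self.varfun(mu)
            solver = _HSolver(d, W, inv_var)
            if gnorm < tol:
                return u, pll, solver
            step = solver.solve(g)
            # step-halving to guarantee ascent of the penalized log-likelihood
            t = 1.0
            for _ in range(30):
                u_new = [uf + t * sf for uf, sf in zip(u, step)]
                eta = self._eta(beta, u_new)
                pll_new = float(np.sum(self.loglik(d.y, eta))) - 0.5 * sum(
                    iv * float(uf @ uf) for iv, uf in zip(inv_var, u_new)
                )
                if pll_new >= pll - 1e-12:
                    break
                t *= 0.5
            u = u_new
            mu = self.linkinv(eta)
            pll = pll_new
        else:
            warnings.warn("inner Newton iteration did not fully converge")
            solver = _HSolver(d, self.varfun(mu), inv_var)
        return u, pll, solver

    def __call__(self, theta: np.ndarray) -> float:
        """Negative Laplace log-likelihood at theta = (beta, log-sds)."""
        d = self.d
        p = d.p
        beta = theta[:p]
        log_sd = theta[p:]
        var = np.exp(2.0 * log_sd)
        inv_var = 1.0 / var
        u, pll, solver = self.inner_mode(beta, inv_var)
        self.u_warm = u
        ell = pll - 0.5 * float(np.sum(2.0 * log_sd * np.array([f[2] for f in d.factors])))
        ell -= 0.5 * solver.logdet()
        return -ell

    def value_and_grad(self, theta: np.ndarray):
        """Negative Laplace log-likelihood and its exact gradient.

        The gradient differentiates through the implicitly defined random-effect
        mode (d u-hat / d theta = H^{-1} dF/dtheta from the stationarity
        condition) and through the log-determinant term, whose dependence on the
        linear predictor enters via dW/deta.
        """
        d = self.d
        p = d.p
        beta = theta[:p]
        log_sd = theta[p:]
        inv_var = 1.0 / np.exp(2.0 * log_sd)
        u, pll, solver = self.inner_mode(beta, inv_var)
        self.u_warm = [uf.copy() for uf in u]
        qs = np.array([f[2] for f in d.factors])
        ell = pll - float(np.sum(log_sd * qs)) - 0.5 * solver.logdet()

        eta = self._eta(beta, u)
        mu = self.linkinv(eta)
        W = self.varfun(mu)
        Wp = _weight_prime(self.family, mu)
        resid = d.y - mu
        h = solver.zhz_diag()
        Wph = Wp * h
        grad = np.empty_like(theta)

        def z_apply(x_parts):
            out = np.zeros(d.n)
            for (name, codes, q), xf in zip(d.factors, x_parts):
                out += xf[codes]
            return out

        for j in range(p):
            xj = d.X[:, j]
            rhs = [
                np.bincount(codes, weights=W * xj, minlength=q)
                for (name, codes, q) in d.factors
            ]
            # d u-hat / d beta_j = -H^{-1} Z' W x_j
            z_du = z_apply(solver.solve(rhs)) if d.factors else np.zeros(d.n)
            grad[j] = float(xj @ resid) - 0.5 * float(Wph @ (xj - z_du))

        tr_blocks = solver.inv_trace_blocks()
        for i, ((name, codes, q), uf) in enumerate(zip(d.factors, u)):
            rhs = [np.zeros(f[2]) for f in d.factors]
            rhs[i] = 2.0 * inv_var[i] * uf
            z_du = z_apply(solver.solve(rhs))
            grad[p + i] = (
                inv_var[i] * float(uf @ uf)
                - q
                + inv_var[i] * tr_blocks[i]
                - 0.5 * float(Wph @ z_du)
            )
        if not (np.isfinite(ell) and np.all(np.isfinite(grad))):
            # overflow during a line-search probe (e.g. exp of an extreme
            # Poisson linear predictor): report a very poor objective so the
            # optimizer backtracks
            return 1e10, np.zeros_like(theta)
        return -ell, -grad


def _irls_start(design: _Design, family: str, ridge=1e-6, n_iter=25) -> np.ndarray:
    """Plain GLM IRLS (no random effects) for starting values."""
    loglik, linkinv, varfun = _family_funcs(family)
    X, y = design.X, design.y
    beta = np.zeros(design.p)
    if family == "binomial":
        beta[:] = 0.0
    for _ in range(n_iter):
        eta = X @ beta + design.offset
        mu = linkinv(eta)
        W = np.clip(varfun(mu), 1e-10, None)
        z = eta - design.offset + (y - mu) / W
        XtW = X.T * W
        H = XtW @ X + ridge * np.eye(design.p)
        beta_new = np.linalg.solve(H, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _beta_cov(design: _Design, family: str, beta, u, inv_var):
    """Conditional covariance of the fixed effects at the fitted parameters."""
    loglik, linkinv, varfun = _family_funcs(family)
    eta = design.X @ beta + design.offset
    for (name, codes, q), uf in zip(design.factors, u):
        eta = eta + uf[codes]
    W = varfun(linkinv(eta))
    X = design.X
    XtWX = (X.T * W) @ X
    if not design.factors:
        return np.linalg.inv(XtWX)
    solver = _HSolver(design, W, inv_var)
    # X'WZ blocks, one (p, q_f) matrix per factor
    XtWZ = []
    for name, codes, q in design.factors:
        M = np.empty((design.p, q))
        for j in range(design.p):
            M[j] = np.bincount(codes, weights=W * X[:, j], minlength=q)
        XtWZ.append(M)
    corr = np.zeros((design.p, design.p))
    for j in range(design.p):
        sol = solver.solve([M[j] for M in XtWZ])
        corr[j] = sum(M @ s for M, s in zip(XtWZ, sol))
    return np.linalg.inv(XtWX - corr)


# ---------------------------------------------------------------------------
# Gaussian exact marginal ML
# ---------------------------------------------------------------------------

class _GaussianML:
    """Exact ML for the Gaussian linear mixed model via Woodbury identities."""

    def __init__(self, design: _Design):
        self.d = design
        self.q_tot = sum(f[2] for f in design.factors)
        # Z'Z and Z'X, Z'y computed once
        self.ZtX = self._zt_mat(design.X)
        self.Zty = self._zt_vec(design.y)
        self.ZtZ = self._ztz()

    def _zt_vec(self, v):
        parts = [
            np.bincount(codes, weights=v, minlength=q)
            for (name, codes, q) in self.d.factors
        ]
        return np.concatenate(parts) if parts else np.zeros(0)

    def _zt_mat(self, M):
        return np.column_stack([self._zt_vec(M[:, j]) for j in range(M.shape[1])]) \
            if M.shape[1] else np.zeros((self.q_tot, 0))

    def _ztz(self):
        f = self.d.factors
        if not f:
            return np.zeros((0, 0))
        qs = [fa[2] for fa in f]
        Z = np.zeros((self.q_tot, self.q_tot))
        off = np.concatenate([[0], np.cumsum(qs)])
        for i, (ni, ci, qi) in enumerate(f):
            counts = np.bincount(ci, minlength=qi)
            Z[off[i]:off[i + 1], off[i]:off[i + 1]] = np.diag(counts.astype(float))
        if len(f) == 2:
            (n1, c1, q1), (n2, c2, q2) = f
            cross = np.bincount(c1 * q2 + c2, minlength=q1 * q2).reshape(q1, q2)
            Z[:q1, q1:] = cross
            Z[q1:, :q1] = cross.T
        return Z

    def profiled_negloglik(self, theta, return_fit=False):
        if not return_fit:
            # numeric-gradient probes can hit numerically singular corners;
            # report them as very poor rather than fatal
            try:
                out = self._profiled(theta, False)
            except np.linalg.LinAlgError:
                return 1e10
            return out if np.isfinite(out) else 1e10
        return self._profiled(theta, True)

    def _profiled(self, theta, return_fit):
        d = self.d
        s2e = np.exp(2.0 * theta[0])
        s2f = np.exp(2.0 * theta[1:])
        n = d.n
        if self.q_tot:
            Ginv = np.concatenate(
                [np.full(f[2], 1.0 / s2f[i]) for i, f in enumerate(d.factors)]
            )
            K = np.diag(Ginv) + self.ZtZ / s2e
            L = np.linalg.cholesky(K)
            logdet_sigma = (
                n * np.log(s2e)
                + 2.0 * np.sum(np.log(np.diag(L)))
                + float(np.sum(np.log(1.0 / Ginv)))
            )

            def sigma_inv(Ab, ZtA):
                # Sigma^{-1} A given A and Z'A
                return Ab / s2e - self._z_apply(_chol_solve(L, ZtA / s2e)) / s2e
        else:
            logdet_sigma = n * np.log(s2e)

            def sigma_inv(Ab, ZtA):
                return Ab / s2e

        SiX = np.column_stack(
            [sigma_inv(d.X[:, j], self.ZtX[:, j]) for j in range(d.p)]
        )
        Siy = sigma_inv(d.y, self.Zty)
        XtSiX = d.X.T @ SiX
        XtSiy = d.X.T @ Siy
        beta = np.linalg.solve(XtSiX, XtSiy)
        r = d.y - d.X @ beta
        Sir = Siy - SiX @ beta
        quad = float(r @ Sir)
        ell = -0.5 * (n * np.log(2.0 * np.pi) + logdet_sigma + quad)
        if return_fit:
            cov = np.linalg.inv(XtSiX)
            return ell, beta, cov, s2e, s2f
        return -ell

    def _z_apply(self, v):
        out = np.zeros(self.d.n)
        off = 0
        for name, codes, q in self.d.factors:
            out += v[off:off + q][codes]
            off += q
        return out


def _fit_gaussian(spec: ModelSpec, design: _Design, tol: float) -> FitResult:
    eng = _GaussianML(design)
    sd_y = float(np.std(design.y)) or 1.0
    # method-of-moments starting values from the OLS residuals
    beta_ols, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    resid = design.y - design.X @ beta_ols
    var_r = float(np.var(resid)) or sd_y ** 2
    nf = len(design.factors)
    v0 = []
    for name, codes, q in design.factors:
        counts = np.bincount(codes, minlength=q).astype(float)
        gm = np.bincount(codes, weights=resid, minlength=q) / np.maximum(counts, 1.0)
        v0.append(max(float(np.var(gm)) - var_r / max(counts.mean(), 1.0), 0.01 * var_r))
    s2e0 = max(var_r - sum(v0), 0.1 * var_r)
    x0 = 0.5 * np.log(np.concatenate([[s2e0], v0])) if nf else 0.5 * np.log([s2e0])
    lb = np.log(np.concatenate([[sd_y * 1e-6 + 1e-12], np.full(nf, sd_y * _SD_LOWER + 1e-12)]))
    ub = np.log(np.full(1 + nf, sd_y * _SD_UPPER + 1.0))
    bounds = list(zip(lb, ub))
    # Nelder-Mead is robust to the steep boundary walls of the profile
    # likelihood in <=3 dimensions; a quasi-Newton polish sharpens the optimum
    res = optimize.minimize(
        eng.profiled_negloglik,
        np.clip(x0, lb, ub),
        method="Nelder-Mead",
        bounds=bounds,
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
    )
    res2 = optimize.minimize(
        eng.profiled_negloglik,
        res.x,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 200},
    )
    # an abnormal line-search exit in the polish is benign when Nelder-Mead
    # already converged; report success if either stage did
    success = bool(res.success or res2.success)
    if res2.fun <= res.fun:
        res = res2
    ell, beta, cov, s2e, s2f = eng.profiled_negloglik(res.x, return_fit=True)
    vcomp, boundary = {}, {}
    for i, (name, codes, q) in enumerate(design.factors):
        sd = float(np.sqrt(s2f[i]))
        boundary[name] = sd < _BOUNDARY_SD * sd_y
        vcomp[name] = float(s2f[i])
    return FitResult(
        spec=spec,
        params=beta,
        param_names=design.names,
        se=np.sqrt(np.diag(cov)),
        vcomp=vcomp,
        scale=float(s2e),
        loglik=float(ell),
        n_obs=design.n,
        n_groups={f[0]: f[2] for f in design.factors},
        converged=success,
        boundary=boundary,
        design_info=design.design_info,
        group_levels=design.group_levels,
        dropped_columns=design.dropped,
        cov_params=cov,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def fit_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    *,
    var_fixed: Optional[dict] = None,
    n_restarts: int = 3,
    tol: float = 1e-8,
) -> FitResult:
    """Fit a random-intercept GLMM by maximum likelihood.

    ``var_fixed`` pins named variance components to fixed values; pinning a
    component to 0 removes it from the integration (the model degenerates to
    an ordinary GLM when all components are 0).  Boundary estimates
    (variance -> 0) are flagged, not raised.
    """
    var_fixed = dict(var_fixed or {})
    pinned_zero = {g for g, v in var_fixed.items() if v == 0.0}
    eff_groups = tuple(g for g in spec.groups if g not in pinned_zero)
    eff_spec = ModelSpec(spec.formula, eff_groups, spec.family, spec.offset)
    design = _Design(eff_spec, data)

    if spec.family == "gaussian":
        fit = _fit_gaussian(eff_spec, design, tol)
    else:
        fit = _fit_laplace(eff_spec, design, var_fixed, n_restarts, tol)

    # report pinned-to-zero components as 0-variance entries for transparency
    for g in spec.groups:
        if g in pinned_zero:
            fit.vcomp[g] = 0.0
            fit.boundary[g] = True
            fit.n_groups[g] = int(pd.Series(data[g]).nunique())
    fit = FitResult(**{**fit.__dict__, "spec": spec})
    return fit


def _fit_laplace(spec, design, var_fixed, n_restarts, tol):
    obj = _LaplaceObjective(design, spec.family)
    p = design.p
    nf = len(design.factors)
    fixed_sd = {}
    for g, v in var_fixed.items():
        if v > 0:
            fixed_sd[g] = np.sqrt(v)

    beta0 = _irls_start(design, spec.family)
    rng = np.random.default_rng(0)
    trace = []
    best = None
    for attempt in range(max(1, n_restarts)):
        if attempt == 0:
            x0 = np.concatenate([beta0, np.full(nf, np.log(0.3))])
        else:
            x0 = np.concatenate(
                [
                    beta0 + rng.normal(0, 0.2, size=p),
                    np.log(rng.uniform(0.05, 1.0, size=nf)),
                ]
            )
        obj.u_warm = [np.zeros(f[2]) for f in design.factors]
        bounds = [(None, None)] * p + [(np.log(_SD_LOWER), np.log(_SD_UPPER))] * nf
        # hold pinned positive components at their value via equal bounds
        for i, (name, codes, q) in enumerate(design.factors):
            if name in fixed_sd:
                v = np.log(fixed_sd[name])
                bounds[p + i] = (v, v)
                x0[p + i] = v
        try:
            res = optimize.minimize(
                obj.value_and_grad,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-6, "maxiter": 1000, "maxcor": 25},
            )
        except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
            trace.append(f"attempt {attempt}: linear algebra failure: {e}")
            continue
        trace.append(
            f"attempt {attempt}: status={res.status} nll={res.fun:.6f} nit={res.nit}"
        )
        if not np.isfinite(res.fun) or res.fun >= 1e9:
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success:
            break
    if best is None:
        raise ConvergenceError("all optimisation attempts failed", trace)

    theta = best.x
    beta = theta[:p]
    log_sd = theta[p:]
    var = np.exp(2.0 * log_sd)
    inv_var = 1.0 / var
    obj.u_warm = [np.zeros(f[2]) for f in design.factors]
    u, _, _ = obj.inner_mode(beta, inv_var)
    cov = _beta_cov(design, spec.family, beta, u, inv_var)
    vcomp, boundary = {}, {}
    for i, (name, codes, q) in enumerate(design.factors):
        sd = float(np.sqrt(var[i]))
        boundary[name] = sd < _BOUNDARY_SD * 2  # logit/log scale
        vcomp[name] = float(var[i])
    return FitResult(
        spec=spec,
        params=beta,
        param_names=design.names,
        se=np.sqrt(np.diag(cov)),
        vcomp=vcomp,
        scale=None,
        loglik=float(-best.fun),
        n_obs=design.n,
        n_groups={f[0]: f[2] for f in design.factors},
        converged=bool(best.success),
        boundary=boundary,
        design_info=design.design_info,
        group_levels=design.group_levels,
        dropped_columns=design.dropped,
        cov_params=cov,
    )


def laplace_loglik(spec: ModelSpec, data: pd.DataFrame, params: dict) -> float:
    """Laplace-approximate marginal log-likelihood at fixed parameters.

    Companion to :func:`brute_force_loglik` for validating the approximation
    at a chosen point (``beta``, ``variances``) rather than at the optimum.
    """
    if spec.family == "gaussian":
        raise GlmmError("gaussian marginal likelihood is exact; no Laplace path")
    variances = params.get("variances", {})
    active = tuple(g for g in spec.groups if variances.get(g, 0.0) > 0)
    eff_spec = ModelSpec(spec.formula, active, spec.family, spec.offset)
    design = _Design(eff_spec, data)
    beta = np.asarray(params["beta"], dtype=float)
    obj = _LaplaceObjective(design, spec.family)
    log_sd = np.array([0.5 * np.log(variances[f[0]]) for f in design.factors])
    return -obj(np.concatenate([beta, log_sd]))


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_loglik(
    spec: ModelSpec,
    data: pd.DataFrame,
    params: dict,
    *,
    gh_points: int = 101,
    max_grid: int = 200_000,
) -> float:
    """Marginal log-likelihood by dense numerical integration over the random
    effects at fixed parameters.

    ``params`` holds ``beta`` (aligned with the design columns), ``variances``
    (factor name -> sigma^2) and, for the Gaussian family, ``scale`` (residual
    variance).  One grouping factor integrates group-by-group with
    Gauss-Hermite quadrature (high accuracy).  Two crossed factors use a
    product Gauss-Hermite grid over all random effects, feasible only when the
    total number of levels is small (<= ~6); accuracy then degrades to roughly
    1e-4 in log-likelihood.  Larger instances raise.
    """
    design = _Design(spec, data)
    beta = np.asarray(params["beta"], dtype=float)
    if beta.shape != (design.p,):
        raise GlmmError(f"beta must have length {design.p}")
    variances = params.get("variances", {})
    sds = [float(np.sqrt(variances.get(f[0], 0.0))) for f in design.factors]
    eta0 = design.X @ beta + design.offset

    if spec.family == "gaussian":
        s2e = float(params["scale"])
        Sigma = s2e * np.eye(design.n)
        for (name, codes, q), sd in zip(design.factors, sds):
            Z = np.zeros((design.n, q))
            Z[np.arange(design.n), codes] = 1.0
            Sigma += sd ** 2 * (Z @ Z.T)
        return float(stats.multivariate_normal.logpdf(design.y, mean=eta0, cov=Sigma))

    loglik, linkinv, varfun = _family_funcs(spec.family)
    active = [(f, sd) for f, sd in zip(design.factors, sds) if sd > 0]
    if not active:
        return float(np.sum(loglik(design.y, eta0)))

    if len(active) == 1:
        (name, codes, q), sd = active[0]
        x, w = hermgauss(gh_points)
        nodes = np.sqrt(2.0) * sd * x          # u values
        logw = np.log(w) - 0.5 * np.log(np.pi)
        total = 0.0
        for g in range(q):
            idx = codes == g
            ll = loglik(design.y[idx, None], eta0[idx, None] + nodes[None, :])
            total += special.logsumexp(ll.sum(axis=0) + logw)
        return float(total)

    # two active factors: product grid over every level of both factors
    qs = [f[0][2] for f in active]
    q_tot = sum(qs)
    if q_tot > 6:
        raise GlmmError(
            f"instance too large for product-grid quadrature ({q_tot} random effects)"
        )
    m = max(5, int(max_grid ** (1.0 / q_tot)))
    m = min(m, 25)
    x, w = hermgauss(m)
    grids = np.meshgrid(*([x] * q_tot), indexing="ij")
    U = np.stack([g.ravel() for g in grids])            # (q_tot, M)
    logw1 = np.log(w) - 0.5 * np.log(np.pi)
    wgrids = np.meshgrid(*([logw1] * q_tot), indexing="ij")
    logW = sum(g.ravel() for g in wgrids)               # (M,)
    eta = np.repeat(eta0[:, None], U.shape[1], axis=1)
    off = 0
    for (name, codes, q), sd in active:
        eta += np.sqrt(2.0) * sd * U[off:off + q][codes, :]
        off += q
    ll = loglik(design.y[:, None], eta).sum(axis=0)
    return float(special.logsumexp(ll + logW))


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def likelihood_ratio_test(
    full: FitResult, reduced: FitResult, *, tol: float = 1e-6, validate_names: bool = True
) -> LRTResult:
    """Chi-square LRT of nested ML fits; negative statistics within convergence
    noise are clipped to 0 with a warning.

    ``validate_names=False`` skips the term-subset check for models that are
    nested structurally rather than by shared column names (e.g. a binary
    season flag as a coarsening of a month factor); the caller is then
    responsible for nesting.
    """
    if full.n_obs != reduced.n_obs:
        raise GlmmError(
            f"row-count mismatch: full has {full.n_obs}, reduced has {reduced.n_obs}"
        )
    if full.spec.family != reduced.spec.family:
        raise GlmmError("family mismatch between full and reduced models")
    if validate_names and not set(reduced.param_names) <= set(full.param_names):
        raise GlmmError("reduced model terms are not a subset of the full model")
    df = full.k_params - reduced.k_params
    if df < 1:
        raise GlmmError("full model must have more parameters than the reduced model")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < 0:
        if chi2 < -tol:
            warnings.warn(
                f"full model log-likelihood below reduced by {-chi2/2:.3g}; "
                "clipping LRT statistic to 0"
            )
        chi2 = 0.0
    return LRTResult(chi2, df, float(stats.chi2.sf(chi2, df)))


def marginal_predict(fit: FitResult, rows: pd.DataFrame) -> np.ndarray:
    """Inverse-link prediction from the fixed effects with random effects at 0."""
    try:
        (X,) = patsy.build_design_matrices([fit.design_info], rows)
    except patsy.PatsyError as e:
        raise GlmmError(f"cannot build design for prediction rows: {e}") from e
    X = np.asarray(X, dtype=float)
    cols = [fit.design_info.column_names.index(n) for n in fit.param_names]
    eta = X[:, cols] @ fit.params
    if fit.spec.family == "binomial":
        return special.expit(eta)
    if fit.spec.family == "poisson":
        return np.exp(eta)
    return eta


def wald_test(fit: FitResult, terms: Sequence[str]) -> dict:
    """Joint Wald test that a set of coefficients is 0 (chi-square and F form)."""
    if fit.cov_params is None:
        raise GlmmError("fit does not carry a coefficient covariance matrix")
    idx = [fit.param_names.index(t) for t in terms]
    b = fit.params[idx]
    V = fit.cov_params[np.ix_(idx, idx)]
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return {
        "chi_square": chi2,
        "df": df,
        "F": chi2 / df,
        "p_value": float(stats.chi2.sf(chi2, df)),
    }
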