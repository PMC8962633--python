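"""REML linear mixed model for standardised fitness with random-term LRTs.

The model is::

    value ~ Sex + Sex.Ratio + Sex:Sex.Ratio
            + (1 | line) + (1 | line:sex) + (1 | line:sex_ratio)
            + (1 | line:sex:sex_ratio)

fitted by restricted maximum likelihood. Every random term is a hemigenome
line effect or one of its interactions, so the marginal covariance is block
diagonal by line and the REML criterion is accumulated block-wise; variance
components are optimised on the log scale (non-negativity by construction)
with a quasi-Newton method from three fixed starting points, keeping the
best. A component driven to the lower bound is reported as a boundary
(singular) fit at 0, not an error.

Significance of each random term is assessed by an ANOVA-like table of
likelihood-ratio tests: the model is refitted without the term and
LRT = 2 (logLik_full - logLik_reduced) is referred to a chi-square with one
degree of freedom (the 50:50 boundary mixture halves these p-values and is
available via ``mixture=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .data import FitnessTable
from .transforms import StandardizedTable, standardize_for_lmm

_LOG2PI = np.log(2 * np.pi)
_BOUND = (-30.0, 8.0)  # log-variance box; lower edge ~ variance 1e-13
_BOUNDARY_TOL = 1e-8


@dataclass
class RemlFit:
    """Raw output of :func:`reml_fit`."""

    variance_components: np.ndarray  # one per random factor
    residual_variance: float
    llf: float  # REML log-likelihood
    beta: np.ndarray
    beta_cov: np.ndarray
    converged: bool
    n_iter: int
    n_obs: int
    n_fixed: int

    @property
    def n_par(self) -> int:
        return self.n_fixed + len(self.variance_components) + 1


def _block_partition(factors: list[np.ndarray], groups: np.ndarray | None, n: int):
    """Row index lists per independent block of the marginal covariance."""
    if groups is None:
        return [np.arange(n)]
    order = np.argsort(groups, kind="stable")
    g = groups[order]
    starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
    blocks = np.split(order, starts[1:])
    for f in factors:  # levels of every factor must not straddle blocks
        level_group = {}
        for lev, grp in zip(f, groups):
            if level_group.setdefault(lev, grp) != grp:
                raise ValueError("random factor level spans more than one group")
    return blocks


def _prepare_blocks(y, X, factors, groups):
    """Split rows into independent blocks with per-block Z_t Z_t' matrices."""
    n = len(y)
    blocks = _block_partition(factors, groups, n)
    block_data = []
    for idx in blocks:
        mats = []
        for f in factors:
            fb = f[idx]
            mats.append((fb[:, None] == fb[None, :]).astype(float))
        block_data.append((y[idx], X[idx], mats, len(idx)))
    return block_data


def _make_objective(y, X, factors, groups):
    """Build the REML criterion -2 logLik(theta) with its exact gradient on
    the log-variance scale theta = log(sigma2_1..k, sigma2_e).

    d(-2l)/d sigma2_t = tr(P Z_t Z_t') - (Py)' Z_t Z_t' (Py) with
    P = Vinv - Vinv X (X' Vinv X)^-1 X' Vinv, accumulated block-wise.
    """
    n, p = X.shape
    k = len(factors)
    block_data = _prepare_blocks(y, X, factors, groups)

    def neg2_reml_grad(theta):
        vcs, ve = np.exp(theta[:k]), np.exp(theta[k])
        logdetV = 0.0
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        cache = []
        for yb, Xb, mats, nb in block_data:
            V = ve * np.eye(nb)
            for s2, M in zip(vcs, mats):
                V += s2 * M
            try:
                c = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros(k + 1)
            logdetV += 2 * np.log(np.diag(c)).sum()
            Vinv = np.linalg.inv(V)
            u = Vinv @ yb
            W = Vinv @ Xb
            ytvy += yb @ u
            xtvy += Xb.T @ u
            xtvx += Xb.T @ W
            cache.append((Vinv, u, W, mats))
        sign, logdetX = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return 1e12, np.zeros(k + 1)
        A_inv = np.linalg.inv(xtvx)
        b = A_inv @ xtvy
        ypy = ytvy - xtvy @ b
        f = logdetV + logdetX + ypy + (n - p) * _LOG2PI

        grad = np.zeros(k + 1)
        for Vinv, u, W, mats in cache:
            py = u - W @ b  # (Py) restricted to this block
            # P restricted to a block differs from the blockwise expression
            # only through the global A_inv correction
            PB = Vinv - W @ A_inv @ W.T
            for t, M in enumerate(mats):
                grad[t] += np.sum(PB * M) - py @ M @ py
            grad[k] += np.trace(PB) - py @ py
        grad *= np.r_[vcs, ve]  # chain rule for theta = log variance
        return f, grad

    return neg2_reml_grad


def reml_loglik(y, X, factors, variances, residual_variance, groups=None):
    """Restricted log-likelihood at fixed variance components (diagnostics
    and optimality checks; not used by the fitter)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    obj = _make_objective(y, X, factors, groups)
    theta = np.log(np.r_[np.maximum(np.asarray(variances, float), 1e-200),
                         residual_variance])
    return -0.5 * obj(theta)[0]


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    factors: list[np.ndarray],
    groups: np.ndarray | None = None,
    n_starts: int = 3,
    tol: float = 1e-8,
) -> RemlFit:
    """REML estimation for a Gaussian model with independent random
    intercepts per factor and i.i.d. residuals.

    Parameters
    ----------
    y, X : response and fixed-effect design.
    factors : integer level codes, one array per random term.
    groups : optional integer codes; when every factor nests within
        ``groups`` the likelihood is accumulated over the induced blocks.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    k = len(factors)
    neg2_reml_grad = _make_objective(y, X, factors, groups)
    vy = np.var(y) if np.var(y) > 0 else 1.0

    starts = [
        np.log(np.r_[np.full(k, 0.05 * vy), 0.8 * vy]),
        np.log(np.r_[np.full(k, 0.2 * vy), 0.5 * vy]),
        np.log(np.r_[np.full(k, 0.01 * vy), vy]),
    ][:n_starts]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg2_reml_grad, x0, method="L-BFGS-B", jac=True,
            bounds=[_BOUND] * (k + 1),
            options={"ftol": tol * 1e-4, "gtol": 1e-10, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(f"REML optimisation failed: {best.message}")

    vcs, ve = np.exp(best.x[:k]), float(np.exp(best.x[k]))
    # boundary components snap to exact zero
    vcs = np.where(vcs < _BOUNDARY_TOL * vy, 0.0, vcs)

    # GLS fixed effects at the optimum
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    for yb, Xb, mats, nb in _prepare_blocks(y, X, factors, groups):
        V = ve * np.eye(nb)
        for s2, M in zip(vcs, mats):
            V += s2 * M
        c = np.linalg.cholesky(V)
        sol = np.linalg.solve(c, np.column_stack([yb, Xb]))
        xtvy += sol[:, 1:].T @ sol[:, 0]
        xtvx += sol[:, 1:].T @ sol[:, 1:]
    beta_cov = np.linalg.inv(xtvx)
    beta = beta_cov @ xtvy

    return RemlFit(
        variance_components=vcs,
        residual_variance=ve,
        llf=-0.5
        * neg2_reml_grad(np.log(np.r_[np.maximum(vcs, 1e-200), ve]))[0],
        beta=beta,
        beta_cov=beta_cov,
        converged=bool(best.success),
        n_iter=int(best.nit),
        n_obs=n,
        n_fixed=p,
    )


RANDOM_TERMS = ("line", "line:sex", "line:sex_ratio", "line:sex:sex_ratio")


class FitnessLMM:
    """Linear mixed model for per-day standardised fitness.

    Built from a :class:`~hemifit.transforms.StandardizedTable` (or directly
    from a vial-level :class:`~hemifit.data.FitnessTable` via
    :meth:`from_table`, which applies the arcsin-sqrt + per-day scale/centre
    standardisation). ``fit`` returns a :class:`FitnessLMMResults`.
    """

    def __init__(self, std: StandardizedTable):
        df = std.df
        self.std = std
        self.y = df["value"].to_numpy(float)

        cell = df["sex"].astype(str) + ":" + df["sex_ratio"].astype(str)
        cell = pd.Categorical(cell)
        # cell-means coding of Sex + Sex.Ratio + Sex:Sex.Ratio
        self.X = pd.get_dummies(cell, dtype=float).to_numpy()
        self.fixed_names = [f"cell[{c}]" for c in cell.categories]

        line = pd.Categorical(df["line"]).codes.astype(int)
        sex = pd.Categorical(df["sex"]).codes.astype(int)
        ratio = pd.Categorical(df["sex_ratio"]).codes.astype(int)
        self.factors = {
            "line": line,
            "line:sex": line * 2 + sex,
            "line:sex_ratio": line * 3 + ratio,
            "line:sex:sex_ratio": (line * 2 + sex) * 3 + ratio,
        }
        self.groups = line

    @classmethod
    def from_table(cls, table: FitnessTable) -> "FitnessLMM":
        return cls(standardize_for_lmm(table))

    def fit(self, drop: str | None = None, **kwargs) -> "FitnessLMMResults":
        terms = [t for t in RANDOM_TERMS if t != drop]
        raw = reml_fit(
            self.y, self.X, [self.factors[t] for t in terms],
            groups=self.groups, **kwargs,
        )
        if not raw.converged:
            raise RuntimeError("REML fit did not converge")
        return FitnessLMMResults(self, raw, terms)


class FitnessLMMResults:
    """REML estimates plus the ANOVA-like random-term LRT table."""

    def __init__(self, model: FitnessLMM, raw: RemlFit, terms):
        self.model = model
        self._raw = raw
        self.terms = tuple(terms)
        self.variance_components = dict(zip(terms, raw.variance_components))
        self.residual_variance = raw.residual_variance
        self.llf = raw.llf
        self.n_par = raw.n_par
        self.aic = 2 * raw.n_par - 2 * raw.llf
        self.fe_params = pd.Series(raw.beta, index=model.fixed_names)
        self.converged = raw.converged

    def lrt_random_terms(self, mixture: bool = False) -> pd.DataFrame:
        """Refit without each random term in turn; chi-square(1) LRT.

        ``mixture=True`` applies the 50:50 boundary mixture of chi-square(0)
        and chi-square(1), halving the p-values.
        """
        rows = [{
            "term": "<none>", "n_par": self.n_par, "logLik": self.llf,
            "AIC": self.aic, "LRT": np.nan, "Df": np.nan, "p_value": np.nan,
        }]
        for term in self.terms:
            red = self.model.fit(drop=term)
            lrt = max(2.0 * (self.llf - red.llf), 0.0)
            p = chi2.sf(lrt, df=1)
            if mixture:
                p = 0.5 * p
            rows.append({
                "term": f"(1|{term})", "n_par": red.n_par, "logLik": red.llf,
                "AIC": red.aic, "LRT": lrt, "Df": 1, "p_value": p,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        vc = "\n".join(
            f"  {t:<22s} {v:.6f}" for t, v in self.variance_components.items()
        )
        return (
            "REML linear mixed model: standardised fitness\n"
            "=============================================\n"
            f"n_obs = {self._raw.n_obs}, n_par = {self.n_par}, "
            f"REML logLik = {self.llf:.4f}, AIC = {self.aic:.4f}\n"
            f"Variance components:\n{vc}\n"
            f"  {'residual':<22s} {self.residual_variance:.6f}\n"
            f"Fixed (cell means):\n{self.fe_params.to_string(float_format='%.4f')}"
        )
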