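"""Bayesian multivariate animal model for sex-specific fitness.

The observation model for the per-day standardised vial value is::

    W = mu[cell] + L[line, cell] + D[day, line] + eps,   eps ~ N(0, s2_r[cell])

where ``cell`` runs over the six sex x sex-ratio combinations, the line
effect vectors L are MVN(0, G) with an unstructured 6x6 genetic covariance G
(additive genetic variances on the diagonal, intersexual and across-ratio
genetic covariances off it), D is a scalar-variance day x line interaction,
and the residual variance is free per cell. One joint model is fitted over
all cells -- the across-ratio genetic correlations are undefined otherwise.

All full conditionals are conjugate, so the posterior is sampled by Gibbs:
Gaussian updates for mu, L and D, an inverse-Wishart update for G and
inverse-gamma updates for the scalar variances. Priors are weakly
informative: G ~ IW(0.01 I, 7) (a scale far below the unit variance of the
standardised data, with near-minimal degrees of freedom) and
Inv-Gamma(1e-3, 1e-3) on each scalar variance. The study this package
models did not publish its priors or chain settings, so posterior summaries
of real data are reproducible only approximately by construction.

Derived quantities use the hemiclone doubling: the heritability of fitness
in a cell is h2 = 2 s2_g / (s2_r + s2_g) -- the factor 2 converts
between-hemiclone variance to additive genetic variance, and the day x line
variance is excluded from the denominator -- so draws may exceed 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .data import SEX_RATIOS, CELL_LABELS, FitnessTable
from .transforms import StandardizedTable, standardize_for_lmm

logger = logging.getLogger(__name__)

_P = 6  # number of sex x sex-ratio cells
_IW_DF = _P + 1.0
# prior scale well below the unit data scale: an identity-scale IW adds a
# full unit of pseudo-sum-of-squares per cell and repels genetic variances
# from 0, visibly biasing null panels upward at realistic line counts
_IW_SCALE = 0.01
_IG_SHAPE = 1e-3
_IG_SCALE = 1e-3


class AnimalModelVC:
    """Multivariate line-effect ("animal") model on standardised fitness.

    Parameters
    ----------
    std : StandardizedTable
        Per-day scale/centre standardised vial values (mixed-model pathway).

    Use :meth:`from_table` to build directly from raw vial records.
    """

    def __init__(self, std: StandardizedTable):
        df = std.df
        self.std = std
        self.y = df["value"].to_numpy(float)
        self.lines = std.lines
        self.n_lines = len(self.lines)

        cell_lab = df["sex"].astype(str) + "_" + df["sex_ratio"].astype(str)
        self.cell = pd.Categorical(cell_lab, categories=list(CELL_LABELS)).codes.astype(int)
        self.line = pd.Categorical(df["line"], categories=self.lines).codes.astype(int)
        dl_lab = df["day"].astype(str) + "|" + df["line"].astype(str)
        self.dl = pd.Categorical(dl_lab).codes.astype(int)
        self.n_dl = self.dl.max() + 1

        self.n_cell = np.bincount(self.cell, minlength=_P)
        self.lc = self.line * _P + self.cell
        self.n_lc = np.bincount(self.lc, minlength=self.n_lines * _P).reshape(
            self.n_lines, _P
        )
        # each day x line group sits in exactly one cell
        self.dl_cell = np.full(self.n_dl, -1, dtype=int)
        self.dl_cell[self.dl] = self.cell
        self.n_per_dl = np.bincount(self.dl, minlength=self.n_dl)

    @classmethod
    def from_table(cls, table: FitnessTable) -> "AnimalModelVC":
        return cls(standardize_for_lmm(table))

    def fit(
        self,
        chains: int = 3,
        iters: int = 60_000,
        burn_in: int = 10_000,
        thin: int = 50,
        seed: int = 0,
        ess_threshold: float = 200.0,
        iw_scale: float = _IW_SCALE,
        iw_df: float = _IW_DF,
        ig_shape: float = _IG_SHAPE,
        ig_scale: float = _IG_SCALE,
    ) -> "VCResults":
        """Run the Gibbs sampler and return posterior draws + summaries.

        ``iters`` counts total iterations per chain; draws are retained
        every ``thin`` iterations after ``burn_in``. Chains get independent
        seeds spawned from ``seed``. If the effective sample size of any
        reported scalar falls below ``ess_threshold`` a warning is logged
        (diagnostics stay available on the result). The prior arguments
        override the defaults documented in the module docstring.
        """
        if burn_in >= iters:
            raise ValueError("burn_in must be smaller than iters")
        priors = (iw_scale, iw_df, ig_shape, ig_scale)
        seeds = np.random.SeedSequence(seed).spawn(chains)
        per_chain = [
            self._run_chain(iters, burn_in, thin, s, priors) for s in seeds
        ]
        return VCResults(self, per_chain, ess_threshold=ess_threshold,
                         settings=dict(chains=chains, iters=iters,
                                       burn_in=burn_in, thin=thin, seed=seed))

    def _run_chain(self, iters, burn_in, thin, seedseq, priors):
        iw_scale, iw_df, ig_shape, ig_scale = priors
        rng = np.random.default_rng(seedseq)
        y, cell, line, dl = self.y, self.cell, self.line, self.dl
        K, n_dl = self.n_lines, self.n_dl

        mu = np.zeros(_P)
        L = np.zeros((K, _P))
        d = np.zeros(n_dl)
        G = np.eye(_P)
        s2_dl = 0.1
        s2_r = np.ones(_P)

        n_keep = (iters - burn_in + thin - 1) // thin
        out_G = np.empty((n_keep, _P, _P))
        out_s2r = np.empty((n_keep, _P))
        out_s2dl = np.empty(n_keep)
        out_mu = np.empty((n_keep, _P))
        kept = 0

        eyeP = np.eye(_P)
        for it in range(iters):
            inv_r = 1.0 / s2_r

            # cell means (flat prior)
            r = y - L[line, cell] - d[dl]
            sums = np.bincount(cell, r, minlength=_P)
            mu = sums / self.n_cell + rng.standard_normal(_P) * np.sqrt(
                s2_r / self.n_cell
            )

            # line effect vectors, batched over lines
            r = y - mu[cell] - d[dl]
            Ginv = np.linalg.inv(G)
            prec = Ginv[None, :, :] + self.n_lc[:, :, None] * (inv_r * eyeP)[None]
            rhs = np.bincount(self.lc, r * inv_r[cell],
                              minlength=K * _P).reshape(K, _P)
            cf = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs[:, :, None])[:, :, 0]
            z = rng.standard_normal((K, _P))
            # solve L_chol^T x = z per line for a draw with covariance prec^-1
            dev = np.linalg.solve(np.transpose(cf, (0, 2, 1)), z[:, :, None])[:, :, 0]
            L = mean + dev

            # day x line scalar effects
            r = y - mu[cell] - L[line, cell]
            prec_dl = 1.0 / s2_dl + self.n_per_dl * inv_r[self.dl_cell]
            mean_dl = np.bincount(dl, r * inv_r[cell], minlength=n_dl) / prec_dl
            d = mean_dl + rng.standard_normal(n_dl) / np.sqrt(prec_dl)

            # genetic covariance
            G = invwishart.rvs(
                df=iw_df + K, scale=iw_scale * eyeP + L.T @ L, random_state=rng
            )

            # scalar variances
            s2_dl = 1.0 / rng.gamma(ig_shape + 0.5 * n_dl,
                                    1.0 / (ig_scale + 0.5 * (d @ d)))
            resid = y - mu[cell] - L[line, cell] - d[dl]
            ss = np.bincount(cell, resid**2, minlength=_P)
            s2_r = 1.0 / rng.gamma(ig_shape + 0.5 * self.n_cell,
                                   1.0 / (ig_scale + 0.5 * ss))

            if it >= burn_in and (it - burn_in) % thin == 0:
                out_G[kept] = G
                out_s2r[kept] = s2_r
                out_s2dl[kept] = s2_dl
                out_mu[kept] = mu
                kept += 1

        return {"G": out_G[:kept], "s2_r": out_s2r[:kept],
                "s2_dl": out_s2dl[:kept], "mu": out_mu[:kept]}


def _summ(draws: np.ndarray) -> dict:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {"mean": float(np.mean(draws)), "lower": float(lo), "upper": float(hi)}


class VCResults:
    """Posterior draws and derived quantitative-genetic parameters."""

    def __init__(self, model: AnimalModelVC, per_chain: list[dict],
                 ess_threshold: float, settings: dict):
        self.model = model
        self.settings = settings
        self._per_chain = per_chain
        self.G = np.concatenate([c["G"] for c in per_chain])
        self.s2_r = np.concatenate([c["s2_r"] for c in per_chain])
        self.s2_dl = np.concatenate([c["s2_dl"] for c in per_chain])
        self.mu = np.concatenate([c["mu"] for c in per_chain])
        self.n_draws = len(self.G)
        self.ess = self._effective_sample_sizes()
        low = {k: v for k, v in self.ess.items() if v < ess_threshold}
        if low:
            logger.warning(
                "effective sample size below %.0f for: %s",
                ess_threshold,
                ", ".join(f"{k}={v:.0f}" for k, v in low.items()),
            )

    # -- derived quantities, per draw ------------------------------------

    def _cell(self, sex: str, ratio: str) -> int:
        return CELL_LABELS.index(f"{sex}_{ratio}")

    def heritability_draws(self, sex: str, ratio: str) -> np.ndarray:
        c = self._cell(sex, ratio)
        g = self.G[:, c, c]
        return 2.0 * g / (self.s2_r[:, c] + g)

    def heritability(self, sex: str, ratio: str) -> dict:
        """Posterior summary of h2 = 2 s2_g / (s2_r + s2_g) for one cell."""
        return _summ(self.heritability_draws(sex, ratio))

    def correlation_draws(self, cell_a: str, cell_b: str) -> np.ndarray:
        i, j = CELL_LABELS.index(cell_a), CELL_LABELS.index(cell_b)
        return self.G[:, i, j] / np.sqrt(self.G[:, i, i] * self.G[:, j, j])

    def genetic_correlation(self, kind: str, ratio: str | None = None,
                            sex: str | None = None,
                            pair: tuple[str, str] | None = None) -> dict:
        """Posterior summary of a genetic correlation from G.

        ``kind="intersexual"`` needs ``ratio``; ``kind="cross_ratio"`` needs
        ``sex`` and ``pair`` (two sex-ratio labels).
        """
        if kind == "intersexual":
            draws = self.correlation_draws(f"F_{ratio}", f"M_{ratio}")
        elif kind == "cross_ratio":
            a, b = pair
            draws = self.correlation_draws(f"{sex}_{a}", f"{sex}_{b}")
        else:
            raise ValueError(f"unknown kind {kind!r}")
        return _summ(draws)

    def day_line_variance(self) -> dict:
        return _summ(self.s2_dl)

    def difference_draws(self, fn_a, fn_b) -> np.ndarray:
        return fn_a - fn_b

    # -- reporting --------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Table of posterior means and 95% credible intervals for the
        intersexual correlations, heritabilities, across-ratio correlations
        and the day x line variance."""
        rows = []
        for ratio in SEX_RATIOS:
            rows.append({"quantity": f"r_wgmf[{ratio}]",
                         **self.genetic_correlation("intersexual", ratio=ratio)})
        for sex in ("F", "M"):
            for ratio in SEX_RATIOS:
                rows.append({"quantity": f"h2[{sex},{ratio}]",
                             **self.heritability(sex, ratio)})
        for sex in ("F", "M"):
            for a, b in (("MB", "FB"), ("MB", "EQ"), ("EQ", "FB")):
                rows.append({
                    "quantity": f"r_wg[{sex},{a}-{b}]",
                    **self.genetic_correlation("cross_ratio", sex=sex, pair=(a, b)),
                })
        rows.append({"quantity": "var[day:line]", **self.day_line_variance()})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        s = self.settings
        head = (
            f"Multivariate animal model ({s['chains']} chains x {s['iters']} iters, "
            f"burn-in {s['burn_in']}, thin {s['thin']}, seed {s['seed']}; "
            f"{self.n_draws} draws)"
        )
        with pd.option_context("display.float_format", "{:.4f}".format):
            body = self.summary_frame().to_string(index=False)
        return f"{head}\n{'=' * len(head)}\n{body}"

    def draws_frame(self) -> pd.DataFrame:
        """One row per retained draw: G entries, residual and day x line
        variances (plain-CSV exportable)."""
        cols = {}
        for i, a in enumerate(CELL_LABELS):
            for j, b in enumerate(CELL_LABELS):
                if i <= j:
                    cols[f"G[{a},{b}]"] = self.G[:, i, j]
        for i, c in enumerate(CELL_LABELS):
            cols[f"s2_r[{c}]"] = self.s2_r[:, i]
        cols["s2_dayline"] = self.s2_dl
        return pd.DataFrame(cols)

    def _effective_sample_sizes(self) -> dict:
        import arviz as az

        def ess_of(stacked):  # (chain, draw) layout
            return float(az.ess(np.asarray(stacked)))

        out = {}
        nch = len(self._per_chain)
        if min(len(c["G"]) for c in self._per_chain) < 4:
            return {k: np.nan for k in ["s2_dayline"]}
        for i in range(_P):
            out[f"G[{i},{i}]"] = ess_of(
                np.stack([c["G"][:, i, i] for c in self._per_chain])
            )
            out[f"s2_r[{i}]"] = ess_of(
                np.stack([c["s2_r"][:, i] for c in self._per_chain])
            )
        out["s2_dayline"] = ess_of(
            np.stack([c["s2_dl"] for c in self._per_chain])
        )
        return out
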