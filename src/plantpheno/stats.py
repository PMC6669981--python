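"""Weighted randomized-complete-block inference with multiplicity control.

The experimental unit is the pot; the response is a pot-level mean over the
surviving plants, weighted by the number of survivors.  The model is

    response ~ treatment + block

fitted by weighted least squares with a fixed additive block effect by
default (a variance-component random-block option is available; for the
balanced and near-balanced designs used here the two give the same
treatment contrasts).  Many-to-one comparisons against the host-free
control use Dunnett's test with the exact contrast correlation implied by
the design and weights; all-pairs comparisons use the Tukey-Kramer
studentized-range adjustment.

Follows the statsmodels model/results idiom::

    res = BlockDesignModel.from_dataframe(pots, response="gr_ratio").fit()
    res.dunnett(control="control")
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BlockDesignModel",
    "BlockDesignResults",
    "ComparisonResult",
    "CorrelationResult",
    "dunnett_pvalue",
    "tukey_pvalue",
    "paired_t",
    "pearson_r2",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One treatment contrast with its multiplicity-adjusted p-value."""

    contrast: tuple[str, str]  # (level, reference)
    estimate: float
    se: float
    t: float
    df: float
    p_unadjusted: float
    p_adjusted: float
    method: str

    def __post_init__(self):
        if not 0.0 <= self.p_adjusted <= 1.0:
            raise ValueError("adjusted p must be in [0, 1]")
        if self.p_adjusted < self.p_unadjusted - 1e-12:
            raise ValueError("adjusted p cannot be below the unadjusted p")


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    pearson_r: float
    r_squared: float
    n: int


# ---------------------------------------------------------------------------
# multivariate-t tail probabilities for Dunnett's many-to-one comparisons


def _fit_product_correlation(R: np.ndarray, n_iter: int = 200) -> tuple[np.ndarray, float]:
    """Fit R ~ lambda lambda' on the off-diagonal (factor-analytic structure).

    Many-to-one contrasts sharing one control have exactly this structure
    when treatment estimates are independent; weighted block designs are
    near-exact.  Returns (lambda, max off-diagonal residual).
    """
    k = R.shape[0]
    if k == 1:
        return np.array([0.0]), 0.0
    lam = np.full(k, np.sqrt(np.abs(R[~np.eye(k, dtype=bool)]).mean()))
    for _ in range(n_iter):
        num = R @ lam - lam  # row sums over j != i (diag of R is 1)
        denom = lam @ lam - lam**2
        new = np.clip(np.divide(num, denom, out=lam.copy(), where=denom > 0), 0.0, 0.999)
        delta = np.max(np.abs(new - lam))
        lam = new
        if delta < 1e-14:
            break
    resid = R - np.outer(lam, lam)
    np.fill_diagonal(resid, 0.0)
    return lam, float(np.max(np.abs(resid)))


_GH_NODES = 64
_GL_NODES = 48


def _quad_nodes():
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    gh_w = gh_w / np.sqrt(2 * np.pi)  # probabilists' weights -> N(0,1) expectation
    gl_x, gl_w = np.polynomial.legendre.leggauss(_GL_NODES)
    return gh_x, gh_w, 0.5 * (gl_x + 1.0), 0.5 * gl_w


_NODES = _quad_nodes()


def _dunnett_cdf_product(t: float, df: float, lam: np.ndarray) -> float:
    """P(max_i |T_i| <= t) for equicorrelated-by-factor multivariate t.

    T_i = (lam_i Z0 + sqrt(1-lam_i^2) X_i)/U with U = sqrt(chi2_df/df).
    Deterministic Gauss-Hermite (Z0) x Gauss-Legendre (chi quantile)
    quadrature, reproducible to ~1e-8.
    """
    if t <= 0:
        return 0.0
    gh_x, gh_w, q, gl_w = _NODES
    if np.isfinite(df):
        u = np.sqrt(sps.chi2.ppf(q, df) / df)  # (n_u,)
    else:
        u = np.ones_like(q)
    s = np.sqrt(1.0 - lam**2)  # (k,)
    # grids: u (a), z (b), contrast (c)
    tu = t * u[:, None, None]
    lz = lam[None, None, :] * gh_x[None, :, None]
    sc = s[None, None, :]
    inner = sps.norm.cdf((tu - lz) / sc) - sps.norm.cdf((-tu - lz) / sc)
    prod = np.prod(inner, axis=2)  # (n_u, n_z)
    return float(gl_w @ (prod @ gh_w))


def dunnett_pvalue(t: float, df: float, R: np.ndarray, *, seed: int = 0) -> float:
    """Two-sided Dunnett-adjusted p: P(max_i |T_i| >= |t|).

    Uses deterministic quadrature whenever the contrast correlation matrix
    has (near-)product structure; otherwise falls back to seeded
    quasi-Monte-Carlo integration of the multivariate t.
    """
    t = abs(float(t))
    k = R.shape[0]
    if k == 1:
        return float(2.0 * sps.t.sf(t, df))
    lam, resid = _fit_product_correlation(R)
    if resid < 5e-3:
        return float(np.clip(1.0 - _dunnett_cdf_product(t, df, lam), 0.0, 1.0))
    mvt = sps.multivariate_t(shape=R, df=df, allow_singular=True)
    cdf = mvt.cdf(
        np.full(k, t),
        lower_limit=np.full(k, -t),
        random_state=np.random.default_rng(seed),
    )
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def tukey_pvalue(t: float, k: int, df: float) -> float:
    """Tukey(-Kramer) adjusted p from the studentized range: P(q_{k,df} >= sqrt(2)|t|)."""
    if k < 2:
        raise ValueError("Tukey needs at least 2 levels")
    if k == 2:
        return float(2.0 * sps.t.sf(abs(t), df))
    return float(np.clip(sps.studentized_range.sf(np.sqrt(2.0) * abs(t), k, df), 0.0, 1.0))


# ---------------------------------------------------------------------------
# the block-design model


class BlockDesignModel:
    """Weighted two-way model: response ~ treatment + block.

    Parameters
    ----------
    endog : response vector (pot-level phenotype means)
    treatment, block : label vectors, one entry per pot
    weights : observation weights (number of surviving plants per pot);
        rows with weight 0 or missing response are dropped.
    """

    def __init__(self, endog, treatment, block, weights=None):
        endog = np.asarray(endog, dtype=float)
        treatment = np.asarray(treatment, dtype=object)
        block = np.asarray(block, dtype=object)
        n = endog.size
        weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        ok = np.isfinite(endog) & (weights > 0)
        if not ok.any():
            raise ValueError("zero total weight: no usable observations")
        self.endog = endog[ok]
        self.treatment = treatment[ok]
        self.block = block[ok]
        self.weights = weights[ok]
        self.treatment_levels = tuple(pd.unique(pd.Series(self.treatment).sort_values()))
        self.block_levels = tuple(pd.unique(pd.Series(self.block).sort_values()))
        if len(self.treatment_levels) < 2:
            raise ValueError("need at least 2 treatment levels")
        if len(self.block_levels) < 2:
            raise ValueError("need at least 2 blocks")
        for t in self.treatment_levels:
            if not np.any(self.treatment == t):
                raise ValueError(f"treatment {t!r} has no observations")

    @classmethod
    def from_dataframe(
        cls,
        pots: pd.DataFrame,
        response: str,
        treatment: str = "host",
        block: str = "block",
        weights: str | None = "weight",
    ) -> "BlockDesignModel":
        w = pots[weights] if weights is not None and weights in pots.columns else None
        return cls(pots[response], pots[treatment], pots[block], weights=w)

    def _design_matrix(self) -> np.ndarray:
        """Cell-means treatment coding plus sum-to-zero block effects.

        With effect-coded blocks the treatment coefficients are level means
        averaged over blocks — equal to raw treatment means in a balanced,
        equally weighted design.
        """
        k = len(self.treatment_levels)
        nb = len(self.block_levels)
        n = self.endog.size
        X = np.zeros((n, k + nb - 1))
        for j, lvl in enumerate(self.treatment_levels):
            X[self.treatment == lvl, j] = 1.0
        for j, blk in enumerate(self.block_levels[:-1]):
            X[self.block == blk, k + j] = 1.0
        X[self.block == self.block_levels[-1], k:] = -1.0
        return X

    def fit(self, block_effect: str = "fixed") -> "BlockDesignResults":
        """Fit by WLS (fixed block) or REML (random block, unweighted).

        The random-block path uses a single variance component via
        statsmodels MixedLM and ignores weights (the weighted mixed fit is
        out of scope); its treatment contrasts match the fixed path on
        balanced data.
        """
        if block_effect == "fixed":
            return self._fit_fixed()
        if block_effect == "random":
            return self._fit_random()
        raise ValueError("block_effect must be 'fixed' or 'random'")

    def _fit_fixed(self) -> "BlockDesignResults":
        import statsmodels.api as sm

        X = self._design_matrix()
        res = sm.WLS(self.endog, X, weights=self.weights).fit()
        k = len(self.treatment_levels)
        df_resid = self.endog.size - np.linalg.matrix_rank(X)
        if df_resid < 1:
            raise ValueError("no residual degrees of freedom")
        cov = np.asarray(res.cov_params())
        block_var = None
        return BlockDesignResults(
            model=self,
            estimates=dict(zip(self.treatment_levels, res.params[:k])),
            cov_estimates=cov[:k, :k],
            df_resid=float(df_resid),
            scale=float(res.scale),
            block_effect="fixed",
            block_variance=block_var,
        )

    def _fit_random(self) -> "BlockDesignResults":
        import statsmodels.api as sm

        k = len(self.treatment_levels)
        X = np.zeros((self.endog.size, k))
        for j, lvl in enumerate(self.treatment_levels):
            X[self.treatment == lvl, j] = 1.0
        groups = pd.Series(self.block).astype(str).to_numpy()
        md = sm.MixedLM(self.endog, X, groups=groups)
        mres = md.fit(reml=True, method="lbfgs")
        cov = np.asarray(mres.cov_params())[:k, :k]
        df_resid = self.endog.size - k - (len(self.block_levels) - 1)
        return BlockDesignResults(
            model=self,
            estimates=dict(zip(self.treatment_levels, mres.fe_params)),
            cov_estimates=cov,
            df_resid=float(max(df_resid, 1)),
            scale=float(mres.scale),
            block_effect="random",
            block_variance=float(np.asarray(mres.cov_re)[0, 0]),
        )


class BlockDesignResults:
    """Fitted block-design model: level estimates, contrasts, summaries."""

    def __init__(self, model, estimates, cov_estimates, df_resid, scale,
                 block_effect, block_variance=None):
        self.model = model
        self.estimates = estimates
        self.cov_estimates = np.asarray(cov_estimates)
        self.df_resid = df_resid
        self.scale = scale
        self.block_effect = block_effect
        self.block_variance = block_variance

    @property
    def treatment_levels(self):
        return self.model.treatment_levels

    def _contrast(self, a: str, b: str) -> tuple[float, float]:
        """Estimate and SE of (a - b)."""
        lv = list(self.treatment_levels)
        c = np.zeros(len(lv))
        c[lv.index(a)] = 1.0
        c[lv.index(b)] = -1.0
        est = float(c @ np.array([self.estimates[t] for t in lv]))
        var = float(c @ self.cov_estimates @ c)
        return est, float(np.sqrt(var))

    def dunnett(self, control: str, alpha: float = 0.05) -> list[ComparisonResult]:
        """Simultaneous treatment-vs-control comparisons (Dunnett-Hsu).

        Adjusted p-values come from the equicoordinate multivariate t with
        the contrast correlation implied by the actual design and weights,
        honoring unequal replicate allocation.
        """
        lv = list(self.treatment_levels)
        if control not in lv:
            raise ValueError(f"control {control!r} is not a treatment level")
        others = [t for t in lv if t != control]
        if not others:
            raise ValueError("no non-control treatments to compare")
        C = np.zeros((len(others), len(lv)))
        for i, t in enumerate(others):
            C[i, lv.index(t)] = 1.0
            C[i, lv.index(control)] = -1.0
        V = C @ self.cov_estimates @ C.T
        se = np.sqrt(np.diag(V))
        R = V / np.outer(se, se)
        beta = np.array([self.estimates[t] for t in lv])
        est = C @ beta
        tstat = est / se
        out = []
        for i, t in enumerate(others):
            p_un = float(2.0 * sps.t.sf(abs(tstat[i]), self.df_resid))
            p_adj = dunnett_pvalue(tstat[i], self.df_resid, R)
            out.append(
                ComparisonResult(
                    contrast=(t, control),
                    estimate=float(est[i]),
                    se=float(se[i]),
                    t=float(tstat[i]),
                    df=self.df_resid,
                    p_unadjusted=p_un,
                    p_adjusted=max(p_adj, p_un),
                    method="dunnett",
                )
            )
        return out

    def tukey(self, alpha: float = 0.05) -> list[ComparisonResult]:
        """All pairwise comparisons with the Tukey-Kramer adjustment."""
        lv = list(self.treatment_levels)
        k = len(lv)
        out = []
        for i in range(k):
            for j in range(i + 1, k):
                est, se = self._contrast(lv[j], lv[i])
                t = est / se
                p_un = float(2.0 * sps.t.sf(abs(t), self.df_resid))
                p_adj = tukey_pvalue(t, k, self.df_resid)
                out.append(
                    ComparisonResult(
                        contrast=(lv[j], lv[i]),
                        estimate=est,
                        se=se,
                        t=float(t),
                        df=self.df_resid,
                        p_unadjusted=p_un,
                        p_adjusted=max(p_adj, p_un),
                        method="tukey",
                    )
                )
        return out

    def min_adjusted_p(self, method: str, control: str | None = None) -> float:
        """Smallest multiplicity-adjusted p of the family (for FWER studies).

        Adjusted p-values are monotone decreasing in |t|, so the family
        minimum is the adjusted p of the largest |t| — one tail evaluation
        instead of one per contrast.
        """
        lv = list(self.treatment_levels)
        if method == "dunnett":
            if control is None:
                raise ValueError("dunnett needs a control level")
            others = [t for t in lv if t != control]
            C = np.zeros((len(others), len(lv)))
            for i, t in enumerate(others):
                C[i, lv.index(t)] = 1.0
                C[i, lv.index(control)] = -1.0
            V = C @ self.cov_estimates @ C.T
            se = np.sqrt(np.diag(V))
            R = V / np.outer(se, se)
            beta = np.array([self.estimates[t] for t in lv])
            tmax = float(np.max(np.abs(C @ beta) / se))
            return dunnett_pvalue(tmax, self.df_resid, R)
        if method == "tukey":
            k = len(lv)
            tmax = 0.0
            for i in range(k):
                for j in range(i + 1, k):
                    est, se = self._contrast(lv[j], lv[i])
                    tmax = max(tmax, abs(est / se))
            return tukey_pvalue(tmax, k, self.df_resid)
        raise ValueError("method must be 'dunnett' or 'tukey'")

    def comparisons_frame(self, comparisons: list[ComparisonResult]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": [c.contrast[0] for c in comparisons],
                "reference": [c.contrast[1] for c in comparisons],
                "estimate": [c.estimate for c in comparisons],
                "se": [c.se for c in comparisons],
                "t": [c.t for c in comparisons],
                "df": [c.df for c in comparisons],
                "p_unadjusted": [c.p_unadjusted for c in comparisons],
                "p_adjusted": [c.p_adjusted for c in comparisons],
                "method": [c.method for c in comparisons],
            }
        )

    def summary(self) -> str:
        lines = [
            "Block-design model (response ~ treatment + block)",
            f"  block effect: {self.block_effect}"
            + (f" (var = {self.block_variance:.4g})" if self.block_variance is not None else ""),
            f"  n = {self.model.endog.size}, residual df = {self.df_resid:.0f}, "
            f"scale = {self.scale:.4g}",
            "  treatment estimates (weighted level means):",
        ]
        se = np.sqrt(np.diag(self.cov_estimates))
        for lvl, s in zip(self.treatment_levels, se):
            lines.append(f"    {lvl:>14}: {self.estimates[lvl]: .4f} (se {s:.4f})")
        return "\n".join(lines)

    def plot_estimates(self, ax=None):
        """Point estimates with +-1 SE bars per treatment level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lv = list(self.treatment_levels)
        y = [self.estimates[t] for t in lv]
        err = np.sqrt(np.diag(self.cov_estimates))
        ax.errorbar(range(len(lv)), y, yerr=err, fmt="o", capsize=3)
        ax.set_xticks(range(len(lv)), lv, rotation=45, ha="right")
        ax.set_ylabel("estimate")
        return ax


# ---------------------------------------------------------------------------
# simple tests


def paired_t(x, y) -> ComparisonResult:
    """Two-sided paired t-test on matched observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; p undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return ComparisonResult(
        contrast=("x", "y"),
        estimate=float(d.mean()),
        se=float(sd / np.sqrt(n)),
        t=float(t),
        df=float(n - 1),
        p_unadjusted=p,
        p_adjusted=p,
        method="paired_t",
    )


def pearson_r2(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Sample Pearson correlation and its square."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(
        x_name=x_name, y_name=y_name, pearson_r=r, r_squared=r * r, n=int(x.size)
    )
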