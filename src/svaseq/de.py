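"""Downstream differential expression and the evaluation battery.

DE is per-gene (optionally precision-weighted) least squares of
``log(g + 1)`` on intercept + phenotype + adjustment covariates, with plain
t-tests on the phenotype coefficient and Benjamini-Hochberg q-values.
Precision weights follow the voom idea: estimate the mean-variance trend of
the log-counts with a lowess smoother and weight each observation by the
inverse fourth power of the trend at its fitted value.

Evaluation tools: concordance-at-the-top (CAT) curves between ranked gene
lists, surrogate-truth association (squared correlation for numeric truth,
one-way ANOVA F for categorical truth such as lab of origin), and p-value
calibration summaries.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix, DesignInfo, LatentFactors, SvaseqError
from .transform import TransformSpec, moderated_log


@dataclasses.dataclass
class DEResult:
    """Per-gene DE summary for one primary contrast."""

    table: pd.DataFrame  # index gene_id; coef_primary, t_stat, p_value, q_value
    residual_df: int
    adjust_names: list[str]

    def ranking(self) -> list[str]:
        """Deterministic gene ranking: ascending p, then descending |t|, then id."""
        df = self.table
        order = sorted(
            df.index,
            key=lambda g: (df.at[g, "p_value"], -abs(df.at[g, "t_stat"]), g),
        )
        return order


@dataclasses.dataclass
class CATCurve:
    k_values: np.ndarray
    concordance: np.ndarray

    def at(self, k: int) -> float:
        return float(self.concordance[np.searchsorted(self.k_values, k)])


@dataclasses.dataclass
class ConcordanceResult:
    r2_per_factor: np.ndarray | None = None
    anova_f: np.ndarray | None = None
    anova_p: np.ndarray | None = None


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # running minimum from the right enforces monotonicity
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def voom_like_weights(
    x: CountMatrix,
    design: np.ndarray,
    spec: TransformSpec = TransformSpec(),
) -> np.ndarray:
    """Precision weights from a lowess mean-variance trend.

    Per gene, pair the mean transformed value with the square root of the
    residual standard deviation; smooth the pairs with lowess (span 0.5);
    weight each observation by ``1 / trend(fitted value)^4``, holding the
    trend flat beyond the range of observed means.
    """
    if x.n_genes < 50:
        raise SvaseqError(
            "mean-variance trend estimation needs at least 50 genes; "
            "run fit_de without weights instead"
        )
    xt = moderated_log(x, spec)
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    if n - p < 1:
        raise SvaseqError("no residual degrees of freedom")
    q, _ = np.linalg.qr(design)
    fitted = (xt @ q) @ q.T
    resid = xt - fitted
    sd = np.sqrt(np.sum(resid**2, axis=1) / (n - p))
    mean_t = xt.mean(axis=1)
    smooth = lowess(np.sqrt(sd), mean_t, frac=0.5, return_sorted=True)
    grid_x, grid_y = smooth[:, 0], np.maximum(smooth[:, 1], 1e-6)
    trend = np.interp(np.clip(fitted, grid_x[0], grid_x[-1]), grid_x, grid_y)
    return 1.0 / trend**4


def fit_de(
    x: CountMatrix,
    design: DesignInfo,
    adjust: LatentFactors | np.ndarray | None = None,
    spec: TransformSpec = TransformSpec(),
    use_weights: bool = False,
) -> DEResult:
    """Per-gene linear-model differential expression on log(g + c).

    The primary coefficient's t-statistic uses the gene's own residual
    variance; two-sided p-values come from the t reference with the model's
    residual degrees of freedom.  ``adjust`` appends surrogate variables (or
    a known batch column) to the design.
    """
    design.check_samples(x)
    xt = moderated_log(x, spec)
    m, n = xt.shape
    if isinstance(adjust, LatentFactors):
        adj = adjust.values
        adj_names = list(adjust.factor_ids)
    elif adjust is None:
        adj = np.zeros((n, 0))
        adj_names = []
    else:
        adj = np.asarray(adjust, dtype=float)
        if adj.ndim == 1:
            adj = adj[:, None]
        adj_names = [f"adjust{k + 1}" for k in range(adj.shape[1])]
    dmat = np.hstack([design.full_design, adj])
    p = dmat.shape[1]
    if n - p < 1:
        raise SvaseqError("no residual degrees of freedom for DE")
    if np.linalg.cond(dmat) > 1e8:
        raise SvaseqError(
            "adjustment variables are collinear with the design (condition "
            "number > 1e8); drop or re-estimate the surrogates"
        )
    k0 = design.primary_slice.start  # first primary coefficient
    # residual variance at double-precision noise level counts as zero
    var_floor = (1e-12 * np.maximum(np.abs(xt).max(axis=1), 1.0)) ** 2

    if use_weights:
        weights = voom_like_weights(x, dmat, spec)
        coef = np.empty(m)
        tstat = np.empty(m)
        degenerate = np.zeros(m, dtype=bool)
        for i in range(m):
            w = weights[i]
            sw = np.sqrt(w)
            dw = dmat * sw[:, None]
            yw = xt[i] * sw
            beta, _, _, _ = np.linalg.lstsq(dw, yw, rcond=None)
            resid = yw - dw @ beta
            s2 = resid @ resid / (n - p)
            xtx_inv = np.linalg.inv(dw.T @ dw)
            se = np.sqrt(s2 * xtx_inv[k0, k0])
            coef[i] = beta[k0]
            if s2 <= var_floor[i]:
                coef[i] = 0.0
                tstat[i] = 0.0
                degenerate[i] = True
            else:
                tstat[i] = beta[k0] / se
    else:
        beta, _, _, _ = np.linalg.lstsq(dmat, xt.T, rcond=None)
        resid = xt.T - dmat @ beta
        s2 = np.sum(resid**2, axis=0) / (n - p)
        xtx_inv = np.linalg.inv(dmat.T @ dmat)
        se = np.sqrt(s2 * xtx_inv[k0, k0])
        degenerate = s2 <= var_floor
        coef = np.where(degenerate, 0.0, beta[k0])
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(degenerate, 0.0, beta[k0] / np.where(se == 0, 1.0, se))

    pval = 2.0 * scipy.stats.t.sf(np.abs(tstat), n - p)
    pval[degenerate] = 1.0
    table = pd.DataFrame(
        {
            "coef_primary": coef,
            "t_stat": tstat,
            "p_value": pval,
            "q_value": bh_qvalues(pval),
            "degenerate_variance": degenerate,
        },
        index=x.gene_ids,
    )
    return DEResult(table, residual_df=n - p, adjust_names=adj_names)


def cat_curve(
    ranking_a: list[str], ranking_b: list[str], k_max: int
) -> CATCurve:
    """Concordance-at-the-top: |top_k(a) ∩ top_k(b)| / k for k = 1..k_max."""
    if len(set(ranking_a)) != len(ranking_a) or len(set(ranking_b)) != len(ranking_b):
        raise SvaseqError("rankings must not contain duplicate gene ids")
    if k_max > min(len(ranking_a), len(ranking_b)):
        raise SvaseqError("k_max exceeds ranking length")
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    inter = 0
    conc = np.empty(k_max)
    for k in range(k_max):
        ga, gb = ranking_a[k], ranking_b[k]
        if ga == gb:
            inter += 1
        else:
            if ga in seen_b:
                inter += 1
            if gb in seen_a:
                inter += 1
        seen_a.add(ga)
        seen_b.add(gb)
        conc[k] = inter / (k + 1)
    return CATCurve(np.arange(1, k_max + 1), conc)


def surrogate_association(
    factors: LatentFactors, truth: np.ndarray | list
) -> ConcordanceResult:
    """Association between estimated factors and a ground-truth variable.

    Numeric truth: squared Pearson correlation per factor.  Categorical
    truth (e.g. lab labels): one-way ANOVA of each factor on the levels,
    F = [(RSS0 - RSS1)/(K-1)] / [RSS1/(n-K)].
    """
    vals = factors.values
    n = vals.shape[0]
    truth_arr = np.asarray(truth)
    if len(truth_arr) != n:
        raise SvaseqError("truth length does not match number of samples")
    if truth_arr.dtype.kind in "fiub":
        t = truth_arr.astype(float)
        if np.std(t) == 0:
            raise SvaseqError("truth variable is constant")
        r2 = np.array(
            [np.corrcoef(vals[:, q], t)[0, 1] ** 2 for q in range(vals.shape[1])]
        )
        return ConcordanceResult(r2_per_factor=r2)
    labels = truth_arr.astype(str)
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise SvaseqError("categorical truth needs at least 2 levels")
    if np.any(counts < 2):
        raise SvaseqError("every level needs at least 2 samples")
    k = len(levels)
    fs = np.empty(vals.shape[1])
    ps = np.empty(vals.shape[1])
    for qi in range(vals.shape[1]):
        v = vals[:, qi]
        rss0 = np.sum((v - v.mean()) ** 2)
        rss1 = sum(
            np.sum((v[labels == lev] - v[labels == lev].mean()) ** 2)
            for lev in levels
        )
        fs[qi] = ((rss0 - rss1) / (k - 1)) / (rss1 / (n - k)) if rss1 > 0 else np.inf
        ps[qi] = scipy.stats.f.sf(fs[qi], k - 1, n - k)
    return ConcordanceResult(anova_f=fs, anova_p=ps)


def pvalue_calibration(p: np.ndarray, alpha: float = 0.05) -> dict[str, float]:
    """Empirical rejection rate at alpha and the KS distance from Uniform(0,1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise SvaseqError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise SvaseqError("p-values must lie in [0, 1]")
    ks = scipy.stats.kstest(p, "uniform").statistic
    return {
        "proportion_below_alpha": float(np.mean(p < alpha)),
        "ks_statistic_vs_uniform": float(ks),
    }
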