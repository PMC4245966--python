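"""Surrogate variable estimation for sequencing data.

The model behind everything here: on the moderated-log scale, expression of
gene i in sample j decomposes into a baseline, effects of modelled
phenotype/adjustment variables, effects of Q unknown sample-level artifacts
u, and noise.  Because artifacts act on many genes at once, genes that carry
artifact signal but no phenotype signal let us estimate (a linear
transformation of) u by a weighted singular value decomposition — which is
all downstream adjustment needs.

Three estimation flavours are provided:

``irw``
    Iteratively re-weighted: alternate between estimating per-gene
    probabilities λ_i of "affected by artifacts but not by the phenotype"
    and extracting factors from the λ-weighted, row-centered data.
``two_step``
    Detect artifact-associated genes once from the residual eigen-factors
    (BH-adjusted F-test, λ ∈ {0,1}), then extract factors from that subset.
``supervised``
    λ_i = 1 exactly for annotated negative-control genes, 0 otherwise; a
    single weighted extraction.  Never uses the phenotype labels, which
    makes it robust to phenotype–artifact confounding.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
import scipy.stats
from sklearn.isotonic import IsotonicRegression

from .io import CountMatrix, DesignInfo, GeneSet, LatentFactors, SvaseqError
from .transform import TransformSpec, moderated_log


@dataclasses.dataclass
class WeightVector:
    """Per-gene probabilities λ_i of carrying artifact but not phenotype signal."""

    lam: np.ndarray
    p_artifact: np.ndarray | None = None
    p_primary: np.ndarray | None = None
    mode: str = "empirical"

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        if np.any((self.lam < 0) | (self.lam > 1)):
            raise SvaseqError("weights must lie in [0, 1]")
        if self.mode == "supervised" and not np.all(np.isin(self.lam, (0.0, 1.0))):
            raise SvaseqError("supervised weights must be exactly 0 or 1")


@dataclasses.dataclass
class SvaResult:
    factors: LatentFactors
    weights: WeightVector
    n_sv: int
    method: str
    transform: TransformSpec
    iterations_run: int


# ---------------------------------------------------------------------------
# linear-algebra primitives
# ---------------------------------------------------------------------------

def _design_matrix(design: DesignInfo | np.ndarray) -> np.ndarray:
    if isinstance(design, DesignInfo):
        return design.full_design
    return np.asarray(design, dtype=float)


def residualize(xt: np.ndarray, design: DesignInfo | np.ndarray) -> np.ndarray:
    """Least-squares residuals of every gene row against the sample design.

    Residual rows are orthogonal to each design column.
    """
    xt = np.asarray(xt, dtype=float)
    d = _design_matrix(design)
    n, p = d.shape
    if xt.shape[1] != n:
        raise SvaseqError(f"data has {xt.shape[1]} samples but design has {n} rows")
    if p >= n:
        raise SvaseqError("design must have fewer columns than samples")
    if np.linalg.matrix_rank(d) < p:
        raise SvaseqError("design matrix is rank deficient")
    q, _ = np.linalg.qr(d)
    return xt - (xt @ q) @ q.T


def _svd_right(x: np.ndarray, q: int) -> np.ndarray:
    """Top-q right singular vectors (n x q), deterministic sign."""
    _, _, vt = scipy.linalg.svd(x, full_matrices=False)
    v = vt[:q].T
    return _fix_signs(v)


def _fix_signs(v: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    v = v.copy()
    for k in range(v.shape[1]):
        j = np.argmax(np.abs(v[:, k]))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    return v


def block_f_pvalues(
    xt: np.ndarray, full: np.ndarray, reduced: np.ndarray
) -> np.ndarray:
    """Per-gene F-test p-values comparing nested sample-level designs.

    Vectorized over genes: residual sums of squares come from projections
    onto orthonormal bases of the two design column spaces.
    """
    xt = np.asarray(xt, dtype=float)
    full = np.asarray(full, dtype=float)
    reduced = np.asarray(reduced, dtype=float)
    n = xt.shape[1]
    p1 = np.linalg.matrix_rank(full)
    p0 = np.linalg.matrix_rank(reduced)
    if p1 <= p0:
        raise SvaseqError("full design adds no columns beyond the reduced design")
    if n - p1 < 1:
        raise SvaseqError("no residual degrees of freedom for the F-test")
    q1 = scipy.linalg.orth(full)
    q0 = scipy.linalg.orth(reduced)
    rss1 = np.sum((xt - (xt @ q1) @ q1.T) ** 2, axis=1)
    rss0 = np.sum((xt - (xt @ q0) @ q0.T) ** 2, axis=1)
    num = np.maximum(rss0 - rss1, 0.0) / (p1 - p0)
    den = rss1 / (n - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    return scipy.stats.f.sf(f, p1 - p0, n - p1)


# ---------------------------------------------------------------------------
# number of surrogate variables
# ---------------------------------------------------------------------------

def estimate_num_sv(
    xt: np.ndarray,
    design: DesignInfo | np.ndarray,
    n_perm: int = 20,
    seed: int = 0,
    alpha: float = 0.10,
) -> int:
    """Permutation parallel analysis for the number of surrogate variables.

    Residualize against the design, compute normalized squared singular
    values s_k^2 / sum(s^2), and compare each leading component with the
    (1 - alpha) quantile of the same statistic under row-wise permutation of
    the data.  Scanning stops at the first component that fails.
    """
    if n_perm < 1:
        raise SvaseqError("n_perm must be at least 1")
    xt = np.asarray(xt, dtype=float)
    d = _design_matrix(design)
    n, p = d.shape
    if xt.shape[0] < 2 or n - p < 2:
        raise SvaseqError("need at least 2 genes and 2 residual degrees of freedom")
    max_q = n - p - 1
    if max_q <= 0:
        return 0

    def _stats(mat: np.ndarray) -> np.ndarray:
        s = scipy.linalg.svdvals(residualize(mat, d)) ** 2
        return s / s.sum()

    observed = _stats(xt)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, observed.size))
    for b in range(n_perm):
        null[b] = _stats(rng.permuted(xt, axis=1))
    thresholds = np.quantile(null, 1.0 - alpha, axis=0)
    q = 0
    for k in range(max_q):
        if observed[k] > thresholds[k]:
            q += 1
        else:
            break
    return q


# ---------------------------------------------------------------------------
# gene weighting
# ---------------------------------------------------------------------------

def lfdr_from_pvalues(p: np.ndarray) -> np.ndarray:
    """Local false discovery rate from a vector of p-values.

    Two-group mixture: pi0 from the 0.8-quantile rule
    ``pi0 = min(1, mean(p > 0.8) / 0.2)``; the marginal density f(p) from a
    boundary-reflected Gaussian kernel estimate on [0, 1]; lfdr = pi0 / f,
    clipped to [0, 1] and made monotone in p by isotonic regression.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 20:
        raise SvaseqError("need at least 20 p-values for a stable lfdr estimate")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise SvaseqError("p-values must lie in [0, 1]")
    pi0 = min(1.0, float(np.mean(p > 0.8)) / 0.2)
    if np.std(p) < 1e-12:
        # degenerate: single atom, uniform-density convention f = 1
        return np.full(p.size, np.clip(pi0, 0.0, 1.0))
    # Silverman bandwidth from the robust scale of p itself: a global
    # (Scott) bandwidth on the reflected sample oversmooths the spike of
    # small p-values that carries all the signal
    iqr = np.subtract(*np.percentile(p, [75, 25]))
    scale = min(np.std(p), iqr / 1.34) if iqr > 0 else np.std(p)
    bw = max(0.9 * scale * p.size ** (-1 / 5), 1e-3)
    reflected = np.concatenate([-p, p, 2.0 - p])
    kde = scipy.stats.gaussian_kde(reflected, bw_method=bw / np.std(reflected))
    density = np.maximum(3.0 * kde(p), 1e-10)
    raw = np.clip(pi0 / density, 0.0, 1.0)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    return iso.fit_transform(p, raw)


def estimate_weights(
    xt: np.ndarray,
    design: DesignInfo,
    factors: LatentFactors | None = None,
    controls: GeneSet | np.ndarray | None = None,
    mode: str = "empirical",
    gene_ids: list[str] | None = None,
) -> WeightVector:
    """Estimate λ_i = P(gene i is affected by artifacts but not phenotype).

    Empirical mode multiplies (1 - lfdr) of the gene's F-test against the
    candidate factors (given the full design) by the lfdr of its F-test
    against the primary variables (given intercept + adjustments + factors).
    Supervised mode is the control-gene indicator.
    """
    xt = np.asarray(xt, dtype=float)
    if mode == "supervised":
        if controls is None:
            raise SvaseqError("supervised weighting requires a control gene set")
        if isinstance(controls, GeneSet):
            if gene_ids is None:
                raise SvaseqError("gene_ids required to resolve a GeneSet")
            mask = np.array([g in controls.ids for g in gene_ids])
        else:
            mask = np.asarray(controls, dtype=bool)
        if not mask.any():
            raise SvaseqError("control gene set is disjoint from the data")
        return WeightVector(mask.astype(float), mode="supervised")
    if mode != "empirical":
        raise SvaseqError(f"unknown weighting mode {mode!r}")
    if factors is None or factors.n_factors < 1:
        raise SvaseqError("empirical weighting requires at least one factor")
    fac = factors.values
    full = design.full_design
    prim = design.primary_columns()
    if prim.shape[1] == 0:
        raise SvaseqError("empirical weighting requires a primary variable")
    p_artifact = block_f_pvalues(xt, np.hstack([full, fac]), full)
    base = np.hstack([design.null_design, fac])
    p_primary = block_f_pvalues(xt, np.hstack([base, prim]), base)
    lam = (1.0 - lfdr_from_pvalues(p_artifact)) * lfdr_from_pvalues(p_primary)
    return WeightVector(np.clip(lam, 0.0, 1.0), p_artifact, p_primary, "empirical")


# ---------------------------------------------------------------------------
# factor extraction
# ---------------------------------------------------------------------------

def factor_extract(
    xt: np.ndarray, weights: WeightVector | np.ndarray, q: int
) -> LatentFactors:
    """Weighted eigengene extraction.

    Row-center the transformed matrix, scale gene row i by λ_i, and return
    the top-q right singular vectors (unit norm, deterministic sign).  With
    unit weights this is exactly PCA of the row-centered matrix.
    """
    xt = np.asarray(xt, dtype=float)
    lam = weights.lam if isinstance(weights, WeightVector) else np.asarray(weights, float)
    m, n = xt.shape
    if lam.shape != (m,):
        raise SvaseqError(f"weights length {lam.size} does not match {m} genes")
    if q > n - 1:
        raise SvaseqError(f"q={q} exceeds n - 1 = {n - 1}")
    if q == 0:
        return LatentFactors(np.zeros((n, 0)))
    if not np.any(lam > 0):
        raise SvaseqError("all weights are zero; nothing to decompose")
    centered = xt - xt.mean(axis=1, keepdims=True)
    return LatentFactors(_svd_right(centered * lam[:, None], q))


# ---------------------------------------------------------------------------
# assembled algorithms
# ---------------------------------------------------------------------------

def svaseq(
    x: CountMatrix,
    design: DesignInfo | None = None,
    method: str = "irw",
    controls: GeneSet | np.ndarray | None = None,
    n_sv: int | str = "auto",
    spec: TransformSpec = TransformSpec(),
    n_iter: int = 5,
    seed: int = 0,
    n_perm: int = 20,
    alpha: float = 0.10,
) -> SvaResult:
    """Run the full surrogate-variable pipeline on a count matrix.

    Parameters
    ----------
    x : CountMatrix
        Gene x sample counts or FPKMs (already filtered if desired).
    design : DesignInfo
        Required for ``irw`` and ``two_step`` (must contain a primary
        variable); optional for ``supervised``.
    method : {"irw", "two_step", "supervised"}
    controls : GeneSet or boolean gene mask, required for ``supervised``.
    n_sv : int or "auto"
        Number of surrogate variables; "auto" runs permutation parallel
        analysis.
    """
    if method not in ("irw", "two_step", "supervised"):
        raise SvaseqError(f"unknown method {method!r}")
    xt = moderated_log(x, spec)
    m, n = xt.shape

    if method == "supervised":
        if controls is None:
            raise SvaseqError("supervised sva requires a control gene set")
        w = estimate_weights(xt, design, controls=controls, mode="supervised",
                             gene_ids=x.gene_ids)
        if n_sv == "auto":
            null_d = (design.null_design if design is not None
                      else np.ones((n, 1)))
            n_sv = estimate_num_sv(xt[w.lam > 0], null_d, n_perm, seed, alpha)
        q = int(n_sv)
        if q == 0:
            return SvaResult(LatentFactors(np.zeros((n, 0))), w, 0,
                             method, spec, 0)
        return SvaResult(factor_extract(xt, w, q), w, q, method, spec, 1)

    if design is None or design.n_primary < 1:
        raise SvaseqError(f"method {method!r} requires a design with a primary "
                          "variable")
    design.check_samples(x)
    full = design.full_design
    resid = residualize(xt, full)
    if n_sv == "auto":
        n_sv = estimate_num_sv(xt, full, n_perm, seed, alpha)
    q = int(n_sv)
    if q == 0:
        w = WeightVector(np.ones(m), mode="empirical")
        return SvaResult(LatentFactors(np.zeros((n, 0))), w, 0, method, spec, 0)

    if method == "two_step":
        from .de import bh_qvalues

        eigen = factor_extract(resid, np.ones(m), q)
        p_artifact = block_f_pvalues(xt, np.hstack([full, eigen.values]), full)
        lam = (bh_qvalues(p_artifact) < 0.05).astype(float)
        w = WeightVector(lam, p_artifact=p_artifact, mode="empirical")
        if not lam.any():
            raise SvaseqError("no genes significantly associated with the "
                              "candidate factors; cannot run two-step sva")
        return SvaResult(factor_extract(xt, w, q), w, q, method, spec, 1)

    # irw
    factors = factor_extract(resid, np.ones(m), q)
    w = WeightVector(np.ones(m), mode="empirical")
    for _ in range(n_iter):
        w = estimate_weights(xt, design, factors, mode="empirical")
        factors = factor_extract(xt, w, q)
    return SvaResult(factors, w, q, method, spec, n_iter)
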