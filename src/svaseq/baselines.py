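"""Comparison estimators: principal components and RUV-style variants.

These are spectral characterizations of the removal-of-unwanted-variation
family — each variant is defined by *which* matrix gets decomposed:

- ``pca``: the full row-centered moderated-log matrix (estimates a mixture
  of phenotype and artifact signal when both are present);
- ``ruv_controls``: the control-gene submatrix;
- ``ruv_empirical``: a submatrix of empirically chosen controls (the genes
  least associated with the primary variable);
- ``ruv_residual``: the residuals after regressing out the full design —
  factors are orthogonal to the phenotype by construction, which is exactly
  why this variant degrades when phenotype and artifact are correlated.

They are deliberately simple eigendecompositions, not re-implementations of
the RUVSeq package's generalized-least-squares estimators.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import CountMatrix, DesignInfo, GeneSet, LatentFactors, SvaseqError
from .sva import _svd_right, block_f_pvalues, residualize
from .transform import TransformSpec, moderated_log


@dataclasses.dataclass(frozen=True)
class BaselineSpec:
    variant: str = "pca"
    q: int = 1
    empirical_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in ("pca", "ruv_controls", "ruv_empirical",
                                "ruv_residual"):
            raise SvaseqError(f"unknown baseline variant {self.variant!r}")
        if not 0 < self.empirical_fraction <= 1:
            raise SvaseqError("empirical_fraction must be in (0, 1]")


def pca_factors(
    x: CountMatrix, spec: TransformSpec = TransformSpec(), q: int = 1
) -> LatentFactors:
    """Top-q right singular vectors of the row-centered moderated-log matrix."""
    xt = moderated_log(x, spec)
    n = xt.shape[1]
    if q > n - 1:
        raise SvaseqError(f"q={q} exceeds n - 1 = {n - 1}")
    if q == 0:
        return LatentFactors(np.zeros((n, 0)))
    centered = xt - xt.mean(axis=1, keepdims=True)
    return LatentFactors(_svd_right(centered, q))


def ruv_factors(
    x: CountMatrix,
    design: DesignInfo | None = None,
    controls: GeneSet | np.ndarray | None = None,
    spec: BaselineSpec = BaselineSpec("ruv_controls"),
    transform_spec: TransformSpec = TransformSpec(),
) -> LatentFactors:
    """RUV-style factor estimation; the variant picks the decomposed matrix."""
    xt = moderated_log(x, transform_spec)
    m, n = xt.shape
    q = spec.q
    if q > n - 1:
        raise SvaseqError(f"q={q} exceeds n - 1 = {n - 1}")
    if q == 0:
        return LatentFactors(np.zeros((n, 0)))

    if spec.variant == "pca":
        return pca_factors(x, transform_spec, q)

    if spec.variant == "ruv_residual":
        if design is None or design.n_primary < 1:
            raise SvaseqError("ruv_residual requires a design with a primary "
                              "variable")
        design.check_samples(x)
        return LatentFactors(_svd_right(residualize(xt, design.full_design), q))

    if spec.variant == "ruv_controls":
        if controls is None:
            raise SvaseqError("ruv_controls requires a control gene set")
        mask = (controls.mask(x) if isinstance(controls, GeneSet)
                else np.asarray(controls, dtype=bool))
        if not mask.any():
            raise SvaseqError("control set is empty after intersection with "
                              "the count matrix")
        sub = xt[mask]
        centered = sub - sub.mean(axis=1, keepdims=True)
        return LatentFactors(_svd_right(centered, q))

    # ruv_empirical: least-primary-associated genes stand in for controls
    if design is None or design.n_primary < 1:
        raise SvaseqError("ruv_empirical requires a design with a primary "
                          "variable")
    design.check_samples(x)
    p = block_f_pvalues(xt, design.full_design, design.null_design)
    n_keep = max(1, int(round(spec.empirical_fraction * m)))
    order = sorted(range(m), key=lambda i: (-p[i], x.gene_ids[i]))
    mask = np.zeros(m, dtype=bool)
    mask[order[:n_keep]] = True
    return ruv_factors(
        x, design, mask,
        BaselineSpec("ruv_controls", q, spec.empirical_fraction),
        transform_spec,
    )
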