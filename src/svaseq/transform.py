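"""Moderated log link and low-count filtering.

Count and FPKM data are strongly right skewed with exact zeros, so latent
structure is estimated on ``log(g + c)`` for a small pseudocount c > 0
(default c = 1).  ``c = 0`` is permitted only when every value is positive.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import CountMatrix, SvaseqError


@dataclasses.dataclass(frozen=True)
class TransformSpec:
    """How to map raw measurements onto the modelling scale.

    kind : {"moderated_log", "identity"}
    constant : pseudocount c added before the natural log
    """

    kind: str = "moderated_log"
    constant: float = 1.0
    log_base: str = "natural"

    def __post_init__(self) -> None:
        if self.kind not in ("moderated_log", "identity"):
            raise SvaseqError(f"unknown transform kind {self.kind!r}")
        if self.log_base != "natural":
            raise SvaseqError("only the natural log base is supported")
        if self.kind == "moderated_log" and self.constant < 0:
            raise SvaseqError("moderated log constant must be >= 0")


def moderated_log(x: CountMatrix | np.ndarray, spec: TransformSpec = TransformSpec()) -> np.ndarray:
    """Apply the transform elementwise; returns a plain (m, n) array.

    The inverse is ``exp(t) - c``; the map is strictly monotone, so within-
    gene ranks are preserved.
    """
    values = x.values if isinstance(x, CountMatrix) else np.asarray(x, dtype=float)
    if spec.kind == "identity":
        return values.copy()
    if spec.constant == 0 and np.any(values <= 0):
        raise SvaseqError("log of zero: constant c = 0 requires all values > 0")
    # log1p keeps precision for small counts (exact for the default c = 1)
    return np.log1p(values + (spec.constant - 1.0))


def inverse_moderated_log(t: np.ndarray, spec: TransformSpec = TransformSpec()) -> np.ndarray:
    if spec.kind == "identity":
        return np.asarray(t, dtype=float).copy()
    return np.expm1(t) - (spec.constant - 1.0)


def filter_low_counts(
    x: CountMatrix, min_count: float = 5.0, min_samples: int = 2
) -> tuple[CountMatrix, list[str]]:
    """Keep genes with value strictly greater than ``min_count`` in at least
    ``min_samples`` samples.  Returns (filtered matrix, kept gene ids).
    """
    if min_samples > x.n_samples:
        raise SvaseqError(
            f"min_samples={min_samples} exceeds sample count {x.n_samples}"
        )
    keep = (x.values > min_count).sum(axis=1) >= min_samples
    if not keep.any():
        raise SvaseqError(
            "all genes removed by the low-count filter; lower min_count or "
            "min_samples"
        )
    kept = x.subset_genes(keep)
    return kept, list(kept.gene_ids)
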