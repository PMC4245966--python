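"""scikit-learn style estimators over the surrogate-variable machinery.

These follow the sklearn convention: samples are rows, genes are columns
(the transpose of the gene x sample orientation used by the functional
API), hyperparameters live in ``__init__``, fitted state carries a trailing
underscore, and ``get_params``/``set_params``/``clone`` work as usual so the
estimators compose with sklearn model selection.

``transform`` removes the estimated surrogate-variable component from the
moderated-log data (the phenotype and adjustment effects are kept), which
is the standard "batch-corrected matrix" people feed to clustering or
visualization.  Surrogates describe the *samples seen at fit time*, so
``transform`` only accepts the fitted data shape.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import baselines as _baselines
from . import sva as _sva
from .io import CountMatrix, DesignInfo, SvaseqError
from .transform import TransformSpec, moderated_log


def _as_counts(X: np.ndarray) -> CountMatrix:
    X = check_array(X, dtype=float, ensure_min_samples=2)
    return CountMatrix(
        X.T,
        [f"g{i}" for i in range(X.shape[1])],
        [f"s{j}" for j in range(X.shape[0])],
    )


def _as_design(n: int, y, covariates) -> DesignInfo:
    primary = pd.DataFrame(index=range(n))
    if y is not None:
        y = np.asarray(y)
        primary = pd.DataFrame({"y": y if y.ndim == 1 else y[:, 0]})
        if y.ndim == 2 and y.shape[1] > 1:
            for k in range(1, y.shape[1]):
                primary[f"y{k}"] = y[:, k]
    adjust = pd.DataFrame(index=range(n))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == 1 and n > 1:
            cov = cov.T
        adjust = pd.DataFrame(
            {f"a{k}": cov[:, k] for k in range(cov.shape[1])}
        )
    return DesignInfo([f"s{j}" for j in range(n)], primary, adjust)


def _control_mask(controls, n_features: int) -> np.ndarray | None:
    if controls is None:
        return None
    arr = np.asarray(controls)
    if arr.dtype == bool:
        if arr.size != n_features:
            raise SvaseqError("control mask length does not match n_features")
        return arr
    mask = np.zeros(n_features, dtype=bool)
    mask[arr.astype(int)] = True
    return mask


class SVA(TransformerMixin, BaseEstimator):
    """Surrogate variable analysis for count/FPKM data.

    Parameters
    ----------
    method : {"irw", "two_step", "supervised"}
        Iteratively re-weighted, two-step, or control-gene supervised
        estimation.
    n_sv : int or "auto"
        Number of surrogate variables; "auto" uses permutation parallel
        analysis.
    constant : float
        Pseudocount c of the moderated log ``log(g + c)``.
    n_iter : int
        Re-weighting iterations for ``method="irw"``.
    alpha : float
        Quantile level of the parallel-analysis null.
    n_perm : int
        Permutations for parallel analysis.
    random_state : int or None
        Seed for the permutation null.

    Attributes
    ----------
    surrogates_ : ndarray of shape (n_samples, n_sv_)
        Estimated surrogate variables (unit-norm columns).
    weights_ : ndarray of shape (n_features,)
        Final per-gene probabilities λ_i.
    n_sv_ : int
        Number of surrogate variables estimated.
    iterations_run_ : int
    """

    def __init__(
        self,
        method: str = "irw",
        n_sv: int | str = "auto",
        constant: float = 1.0,
        n_iter: int = 5,
        alpha: float = 0.10,
        n_perm: int = 20,
        random_state: int | None = None,
    ):
        self.method = method
        self.n_sv = n_sv
        self.constant = constant
        self.n_iter = n_iter
        self.alpha = alpha
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y=None, covariates=None, controls=None):
        """Estimate surrogate variables.

        X : array-like (n_samples, n_features) of non-negative counts/FPKM.
        y : primary phenotype per sample (required for irw/two_step).
        covariates : known adjustment variables, (n_samples, L).
        controls : negative-control genes as a boolean mask or index array
            over features (required for method="supervised").
        """
        counts = _as_counts(X)
        design = _as_design(counts.n_samples, y, covariates)
        mask = _control_mask(controls, counts.n_genes)
        result = _sva.svaseq(
            counts,
            design if (y is not None or covariates is not None) else None,
            method=self.method,
            controls=mask,
            n_sv=self.n_sv,
            spec=TransformSpec(constant=self.constant),
            n_iter=self.n_iter,
            seed=self.random_state or 0,
            n_perm=self.n_perm,
            alpha=self.alpha,
        )
        self.surrogates_ = result.factors.values
        self.weights_ = result.weights.lam
        self.n_sv_ = result.n_sv
        self.iterations_run_ = result.iterations_run
        self.n_features_in_ = counts.n_genes
        self._design = design if y is not None or covariates is not None else None
        return self

    def transform(self, X):
        """Moderated-log data with the surrogate component regressed out."""
        check_is_fitted(self, "surrogates_")
        X = check_array(X, dtype=float)
        if X.shape != (self.surrogates_.shape[0], self.n_features_in_):
            raise SvaseqError(
                "transform expects the matrix the surrogates were fit on "
                f"(shape {(self.surrogates_.shape[0], self.n_features_in_)})"
            )
        xt = moderated_log(X.T, TransformSpec(constant=self.constant))
        if self.n_sv_ == 0:
            return xt.T
        base = (self._design.full_design if self._design is not None
                else np.ones((X.shape[0], 1)))
        dmat = np.hstack([base, self.surrogates_])
        beta, _, _, _ = np.linalg.lstsq(dmat, xt.T, rcond=None)
        sv_part = self.surrogates_ @ beta[base.shape[1]:]
        return (xt.T - sv_part)

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


class PCAFactors(TransformerMixin, BaseEstimator):
    """Principal-component batch estimator (the naive baseline).

    Top right singular vectors of the row-centered moderated-log matrix;
    estimates a linear combination of phenotype and artifact signal.
    """

    def __init__(self, n_sv: int = 1, constant: float = 1.0):
        self.n_sv = n_sv
        self.constant = constant

    def fit(self, X, y=None):
        counts = _as_counts(X)
        factors = _baselines.pca_factors(
            counts, TransformSpec(constant=self.constant), self.n_sv
        )
        self.surrogates_ = factors.values
        self.n_features_in_ = counts.n_genes
        return self

    def transform(self, X):
        check_is_fitted(self, "surrogates_")
        X = check_array(X, dtype=float)
        xt = moderated_log(X.T, TransformSpec(constant=self.constant))
        if self.surrogates_.shape[1] == 0:
            return xt.T
        dmat = np.hstack([np.ones((X.shape[0], 1)), self.surrogates_])
        beta, _, _, _ = np.linalg.lstsq(dmat, xt.T, rcond=None)
        return xt.T - self.surrogates_ @ beta[1:]


class RUVFactors(TransformerMixin, BaseEstimator):
    """RUV-style batch estimators (control, empirical-control, residual).

    variant : {"ruv_controls", "ruv_empirical", "ruv_residual"}
    """

    def __init__(
        self,
        variant: str = "ruv_controls",
        n_sv: int = 1,
        constant: float = 1.0,
        empirical_fraction: float = 0.5,
    ):
        self.variant = variant
        self.n_sv = n_sv
        self.constant = constant
        self.empirical_fraction = empirical_fraction

    def fit(self, X, y=None, covariates=None, controls=None):
        counts = _as_counts(X)
        design = (_as_design(counts.n_samples, y, covariates)
                  if y is not None else None)
        mask = _control_mask(controls, counts.n_genes)
        factors = _baselines.ruv_factors(
            counts,
            design,
            mask,
            _baselines.BaselineSpec(self.variant, self.n_sv,
                                    self.empirical_fraction),
            TransformSpec(constant=self.constant),
        )
        self.surrogates_ = factors.values
        self.n_features_in_ = counts.n_genes
        return self

    def transform(self, X):
        check_is_fitted(self, "surrogates_")
        X = check_array(X, dtype=float)
        xt = moderated_log(X.T, TransformSpec(constant=self.constant))
        if self.surrogates_.shape[1] == 0:
            return xt.T
        dmat = np.hstack([np.ones((X.shape[0], 1)), self.surrogates_])
        beta, _, _, _ = np.linalg.lstsq(dmat, xt.T, rcond=None)
        return xt.T - self.surrogates_ @ beta[1:]

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)
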