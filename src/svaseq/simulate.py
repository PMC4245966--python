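"""Negative-binomial RNA-seq count simulator with group and batch effects.

Counts for gene i in sample j are drawn from a negative binomial with mean

    mu_i * exp(b_i * y_j + d_i * u_j)

and variance ``mu + phi * mu^2`` (phi_i = 0 falls back to Poisson).  y is a
balanced binary group (phenotype) label and u a balanced binary batch label;
the group-batch squared correlation is a controllable design parameter, so
both the orthogonal and the confounded study designs can be generated.  A
designated subset of genes carries batch effect but no group effect — the
ground-truth negative controls.

Baseline means and dispersions can be estimated from any real count matrix
by method of moments, or drawn from built-in log-normal defaults that mimic
the mean/dispersion spread of a typical bulk RNA-seq experiment.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import CountMatrix, DesignInfo, GeneSet, LatentFactors, SvaseqError


@dataclasses.dataclass
class NBGeneParams:
    """Per-gene negative-binomial baseline: mean mu > 0, dispersion phi >= 0."""

    mu: np.ndarray
    phi: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.mu.shape != self.phi.shape:
            raise SvaseqError("mu and phi must have the same length")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.phi))):
            raise SvaseqError("mu and phi must be finite")
        if np.any(self.mu <= 0):
            raise SvaseqError("baseline means must be positive")
        if np.any(self.phi < 0):
            raise SvaseqError("dispersions must be non-negative")

    def __len__(self) -> int:
        return self.mu.size


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    m, n : genes and samples (n even; n divisible by 4 when the group/batch
        table is built internally)
    prop_de : fraction of genes with a group effect (b_i != 0)
    prop_batch : fraction of genes with a batch effect (d_i != 0)
    effect_sd_group, effect_sd_batch : SDs of the natural-log-scale effects
    design_r2 : target squared correlation between group and batch labels
    n_controls : designated negative-control genes (batch effect only)
    """

    m: int = 1000
    n: int = 12
    prop_de: float = 0.3
    prop_batch: float = 0.3
    effect_sd_group: float = 1.0
    effect_sd_batch: float = 1.0
    design_r2: float = 0.0
    n_controls: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.prop_de <= 1 and 0 <= self.prop_batch <= 1):
            raise SvaseqError("prop_de and prop_batch must lie in [0, 1]")
        if self.n % 2:
            raise SvaseqError("n must be even for balanced groups")
        if not 0 <= self.design_r2 <= 1:
            raise SvaseqError("design_r2 must lie in [0, 1]")
        if self.n_controls > int(round(self.m * self.prop_batch)):
            raise SvaseqError(
                f"n_controls={self.n_controls} exceeds the number of "
                f"batch-affected genes {int(round(self.m * self.prop_batch))}"
            )


@dataclasses.dataclass
class SimulatedDataset:
    counts: CountMatrix
    design: DesignInfo
    truth_u: LatentFactors
    truth_coeffs: pd.DataFrame  # columns: b0 (log mu), b1, d, phi
    controls: GeneSet
    null_gene_count: int
    achieved_r2: float
    config: SimConfig

    @property
    def y(self) -> np.ndarray:
        return self.design.primary_columns()[:, 0]

    @property
    def u(self) -> np.ndarray:
        return self.truth_u.values[:, 0]


def default_nb_params(m: int, seed: int = 0) -> NBGeneParams:
    """Built-in log-normal baseline parameters.

    mu_i ~ LogNormal(log 250, 1) and phi_i ~ LogNormal(log 0.1, 0.5): a
    synthetic stand-in with the right orders of magnitude for bulk RNA-seq
    gene means and overdispersions.
    """
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(250.0), 1.0, size=m)
    phi = rng.lognormal(np.log(0.1), 0.5, size=m)
    return NBGeneParams(mu, phi)


def estimate_nb_params(x: CountMatrix) -> NBGeneParams:
    """Method-of-moments per-gene NB parameters from observed counts.

    mu_hat is the sample mean; phi_hat = max(0, (s^2 - mu) / mu^2) with the
    unbiased sample variance.  Genes with zero mean are dropped (count kept
    in ``n_dropped``).
    """
    if x.n_samples < 3:
        raise SvaseqError("need at least 3 samples to estimate NB parameters")
    mu = x.values.mean(axis=1)
    var = x.values.var(axis=1, ddof=1)
    keep = mu > 0
    phi = np.zeros(keep.sum())
    mu_k = mu[keep]
    phi = np.maximum(0.0, (var[keep] - mu_k) / mu_k**2)
    return NBGeneParams(mu_k, phi, n_dropped=int((~keep).sum()))


def make_design(n: int, design_r2: float, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balanced binary group/batch labels with a target squared correlation.

    For balanced margins the 2x2 cell count a (y=1 & u=1) fixes the Pearson
    correlation at r = 4a/n - 1; a is rounded to the nearest feasible
    integer and the achieved r^2 must land within 0.02 of the target.
    Labels are jointly shuffled (seeded), which leaves r^2 unchanged.
    """
    if n % 4:
        raise SvaseqError("n must be divisible by 4 for exact balance")
    r = float(np.sqrt(design_r2))
    a = int(round(n * (1.0 + r) / 4.0))
    a = min(max(a, n // 4), n // 2)
    achieved_r = 4.0 * a / n - 1.0
    if abs(achieved_r**2 - design_r2) > 0.02:
        lo, hi = sorted(((4 * (a - 1) / n - 1) ** 2, achieved_r**2))
        raise SvaseqError(
            f"design_r2={design_r2} infeasible for n={n}; nearest achievable "
            f"values are about {lo:.3f} and {hi:.3f}"
        )
    half = n // 2
    y = np.repeat([0.0, 1.0], half)
    u = np.zeros(n)
    u[half:half + a] = 1.0          # y=1 cell
    u[:half - a] = 1.0              # y=0 cell: half - a ones
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return y[perm], u[perm]


def achieved_design_r2(y: np.ndarray, u: np.ndarray) -> float:
    if np.std(y) == 0 or np.std(u) == 0:
        return 1.0 if np.array_equal(y, u) else 0.0
    return float(np.corrcoef(y, u)[0, 1] ** 2)


def simulate_dataset(
    config: SimConfig,
    params: NBGeneParams | None = None,
    y: np.ndarray | None = None,
    u: np.ndarray | None = None,
) -> SimulatedDataset:
    """Draw one complete dataset (counts + ground truth) from the model.

    ``y``/``u`` override the internal balanced-label construction, e.g. for
    sample sizes not divisible by 4; both must be supplied together.
    """
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = default_nb_params(config.m, seed=config.seed)
    if len(params) < config.m:
        raise SvaseqError(
            f"{len(params)} baseline genes available but m={config.m} requested"
        )
    pick = rng.choice(len(params), size=config.m, replace=False)
    pick.sort()
    mu = params.mu[pick]
    phi = params.phi[pick]

    if (y is None) != (u is None):
        raise SvaseqError("y and u overrides must be supplied together")
    if y is None:
        y, u = make_design(config.n, config.design_r2, seed=config.seed)
    else:
        y = np.asarray(y, dtype=float)
        u = np.asarray(u, dtype=float)
        if y.size != config.n or u.size != config.n:
            raise SvaseqError("y/u overrides must have length n")

    m = config.m
    n_de = int(round(m * config.prop_de))
    n_batch = int(round(m * config.prop_batch))
    de_idx = rng.choice(m, size=n_de, replace=False)
    non_de = np.setdiff1d(np.arange(m), de_idx)
    if config.n_controls > 0:
        control_idx = rng.choice(non_de, size=config.n_controls, replace=False)
    else:
        control_idx = np.array([], dtype=int)
    remaining = np.setdiff1d(np.arange(m), control_idx)
    extra = rng.choice(remaining, size=n_batch - config.n_controls, replace=False)
    batch_idx = np.concatenate([control_idx, extra])

    b1 = np.zeros(m)
    b1[de_idx] = rng.normal(0.0, config.effect_sd_group, size=n_de)
    d = np.zeros(m)
    d[batch_idx] = rng.normal(0.0, config.effect_sd_batch, size=n_batch)
    # controls must carry batch signal; resample exact zeros (prob ~0)
    zero_ctl = control_idx[d[control_idx] == 0.0]
    while zero_ctl.size:
        d[zero_ctl] = rng.normal(0.0, config.effect_sd_batch, size=zero_ctl.size)
        zero_ctl = control_idx[d[control_idx] == 0.0]

    mean = mu[:, None] * np.exp(b1[:, None] * y[None, :] + d[:, None] * u[None, :])
    counts = np.empty((m, config.n))
    poisson = phi == 0
    counts[poisson] = rng.poisson(mean[poisson])
    if (~poisson).any():
        r = 1.0 / phi[~poisson]
        p = r[:, None] / (r[:, None] + mean[~poisson])
        counts[~poisson] = rng.negative_binomial(r[:, None], p)

    gene_ids = [f"gene_{i + 1}" for i in range(m)]
    sample_ids = [f"sample_{j + 1}" for j in range(config.n)]
    cm = CountMatrix(counts, gene_ids, sample_ids, "counts")
    design = DesignInfo(
        sample_ids=sample_ids,
        primary=pd.DataFrame({"group": y}),
        known_adjust=pd.DataFrame(index=range(config.n)),
    )
    truth = pd.DataFrame(
        {"b0": np.log(mu), "b1": b1, "d": d, "phi": phi}, index=gene_ids
    )
    controls = GeneSet(frozenset(gene_ids[i] for i in control_idx))
    # m_u: genes free of phenotype effect (artifact effect allowed)
    null_count = int(np.sum(b1 == 0.0))
    return SimulatedDataset(
        counts=cm,
        design=design,
        truth_u=LatentFactors(u[:, None], ["batch"], kind="true"),
        truth_coeffs=truth,
        controls=controls,
        null_gene_count=null_count,
        achieved_r2=achieved_design_r2(y, u),
        config=config,
    )
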