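"""Synthetic microbiome count data with known differential-abundance truth.

The generator emulates a cross-sectional 16S/shotgun experiment: baseline
absolute abundances ``exp(beta_0k)`` drawn from a three-component gamma
mixture (a majority of moderately abundant taxa, a heavy tail of very
abundant ones), a sparse set ``S`` of truly associated taxa with log fold
changes drawn symmetrically from fold-change intervals ``(1.5, 10)`` and
``(1/10, 1/1.5)``, a sample-specific compositional offset ``d_i`` whose
mean depends on the group through the average absolute signal (so the
sequencing bias is confounded with the variable of interest), and
zero-inflated negative binomial (or Poisson) counts on top.

Defaults follow the study conditions used throughout the validation suite:
dispersion ``phi = 3``, bias scale 0.5 and unit variance of ``d_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data import AbundanceTable, CovariateSet
from .inference import DAResultSet, PipelineSettings, run_mbdecoda

_GAMMA_WEIGHTS = (0.6, 0.3, 0.1)
_GAMMA_SHAPES = (50.0, 200.0, 10_000.0)


@dataclass
class SimulationDesign:
    """All knobs of the data-generating process; the seed fixes everything."""

    n: int = 50
    K: int = 100
    pi: float = 0.2
    x_type: Literal["binary", "normal"] = "binary"
    eta: float | Literal["mixed"] = 0.3
    phi: float = 3.0
    bias_scale: float = 0.5
    confounders: bool = False
    effect_range: tuple[float, float] = (1.5, 10.0)
    generator_model: Literal["ZINB", "ZIP"] = "ZINB"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if 0 < self.pi and self.pi * self.K < 1:
            raise ValueError("pi > 0 but pi * K < 1: no signal taxon can be drawn")
        if isinstance(self.eta, (int, float)) and not 0.0 <= float(self.eta) < 1.0:
            raise ValueError("constant eta must lie in [0, 1)")

    @property
    def signal_set(self) -> np.ndarray:
        return np.arange(math.ceil(round(self.pi * self.K, 9)))


@dataclass
class SimulatedDataset:
    """Generated counts and covariates together with the generating truth."""

    table: AbundanceTable
    cov: CovariateSet
    Delta_true: np.ndarray
    signal_set: np.ndarray
    d_true: np.ndarray
    eta_true: np.ndarray  # per-taxon zero-inflation probability
    beta0_true: np.ndarray
    structural_zeros: np.ndarray = field(default=None)  # n x K indicator


def simulate(design: SimulationDesign) -> SimulatedDataset:
    """Draw one dataset from the design's generative model."""
    rng = np.random.default_rng(design.seed)
    n, K = design.n, design.K

    # baseline log-abundances from the gamma mixture
    comp = rng.choice(3, size=K, p=_GAMMA_WEIGHTS)
    baseline = rng.gamma(shape=np.asarray(_GAMMA_SHAPES)[comp], scale=1.0)
    beta0 = np.log(baseline)

    # sparse effects with random direction: exp(Delta) in (lo, hi) going up,
    # (1/hi, 1/lo) going down, each with probability 1/2
    S = design.signal_set
    Delta = np.zeros(K)
    if S.size:
        lo, hi = design.effect_range
        up = rng.random(S.size) < 0.5
        fold = np.where(
            up,
            rng.uniform(lo, hi, size=S.size),
            rng.uniform(1.0 / hi, 1.0 / lo, size=S.size),
        )
        Delta[S] = np.log(fold)

    if design.x_type == "binary":
        X = np.zeros(n)
        X[n // 2 :] = 1.0  # balanced groups
    elif design.x_type == "normal":
        X = rng.standard_normal(n)
    else:
        raise ValueError(f"unknown x_type {design.x_type!r}")

    if design.confounders:
        C1 = rng.uniform(0.0, 1.0, size=n)
        C2 = rng.binomial(1, 0.5, size=n).astype(float)
        V = np.column_stack([np.ones(n), C1, C2])
        conf_coef = np.tile([1.0, -1.0], (K, 1))
        beta = np.column_stack([beta0, conf_coef])
    else:
        V = np.ones((n, 1))
        beta = beta0[:, None]

    # compositional offset, confounded with X through the mean signal size
    mean_signal = np.abs(Delta[S]).mean() if S.size else 0.0
    d = rng.normal(design.bias_scale * X * mean_signal, 1.0)

    mu = np.exp(d[:, None] + X[:, None] * Delta[None, :] + V @ beta.T)

    if design.eta == "mixed":
        eta_k = np.zeros(K)
        inflated = rng.permutation(K)[K // 2 :]  # exactly ceil(K/2) inflated
        eta_k[inflated] = rng.uniform(0.0, 0.7, size=inflated.size)
    else:
        eta_k = np.full(K, float(design.eta))
    Z = rng.random((n, K)) < eta_k[None, :]

    if design.generator_model == "ZINB":
        # NB(mu, phi) as a gamma-Poisson mixture
        lam = rng.gamma(design.phi, mu / design.phi)
        counts = rng.poisson(lam)
    elif design.generator_model == "ZIP":
        counts = rng.poisson(mu)
    else:
        raise ValueError(f"unknown generator_model {design.generator_model!r}")
    counts = np.where(Z, 0, counts)

    table = AbundanceTable(counts=counts)
    cov = CovariateSet(X=X, U=np.ones((n, 1)), V=V)
    return SimulatedDataset(
        table=table,
        cov=cov,
        Delta_true=Delta,
        signal_set=S,
        d_true=d,
        eta_true=eta_k,
        beta0_true=beta0,
        structural_zeros=Z,
    )


def evaluate(
    result: DAResultSet | "np.ndarray",
    truth: SimulatedDataset,
    fdr_level: float | None = None,
) -> tuple[float, float, int]:
    """Power and empirical FDR of a result set against the known truth.

    Power is the fraction of truly associated taxa declared significant
    (0 when there are none); empirical FDR is the fraction of discoveries
    that are false, with a guarded denominator so no discoveries gives 0.
    """
    df = result.table
    truth_ids = set(np.asarray(truth.table.taxon_ids)[truth.signal_set])
    known = set(truth.table.taxon_ids)
    if not set(df["taxon"]).issubset(known):
        raise ValueError("result taxa do not match the simulated dataset")
    if fdr_level is None:
        discoveries = df.loc[df["significant"], "taxon"]
    else:
        discoveries = df.loc[
            np.isfinite(df["qvalue"]) & (df["qvalue"] <= fdr_level), "taxon"
        ]
    n_disc = len(discoveries)
    true_disc = sum(t in truth_ids for t in discoveries)
    power = true_disc / len(truth_ids) if truth_ids else 0.0
    fdr = (n_disc - true_disc) / max(n_disc, 1)
    return power, fdr, n_disc


def replication_seed(master_seed: int, rep: int) -> int:
    """Derived, independent per-replication seed (counter-based stream)."""
    return int(np.random.SeedSequence([master_seed, rep]).generate_state(1)[0] % 2**31)


def run_replications(
    design: SimulationDesign,
    n_reps: int,
    fdr_level: float = 0.05,
    settings: PipelineSettings | None = None,
) -> dict:
    """Monte-Carlo study: simulate, test and score ``n_reps`` replications.

    Returns mean power and mean empirical FDR with their Monte-Carlo
    standard errors, plus the per-replication values and derived seeds.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    settings = settings or PipelineSettings(fdr_level=fdr_level)
    powers, fdrs, n_discs, seeds = [], [], [], []
    for rep in range(n_reps):
        seed = replication_seed(design.seed, rep)
        seeds.append(seed)
        d = SimulationDesign(**{**design.__dict__, "seed": seed})
        data = simulate(d)
        result = run_mbdecoda(data.table, data.cov, settings=settings)
        power, fdr, n_disc = evaluate(result, data)
        powers.append(power)
        fdrs.append(fdr)
        n_discs.append(n_disc)
    powers = np.asarray(powers)
    fdrs = np.asarray(fdrs)

    def mc_se(x):
        return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")

    return {
        "n_reps": n_reps,
        "fdr_level": fdr_level,
        "mean_power": float(powers.mean()),
        "se_power": mc_se(powers),
        "mean_fdr": float(fdrs.mean()),
        "se_fdr": mc_se(fdrs),
        "mean_discoveries": float(np.mean(n_discs)),
        "powers": powers.tolist(),
        "fdrs": fdrs.tolist(),
        "seeds": seeds,
    }
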