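"""Differential-abundance testing on the debiased effect estimates.

For each taxon the null hypothesis is a zero log fold change.  The test
statistic divides the debiased estimate by a standard error combining the
regression variance of the biased estimate with the variance of the bias
estimate itself (their covariance is negligible when the MCI window is
large):

    t_k = Delta_hat_k / sqrt(var(Delta_tilde_k) + var(gamma_hat))

Two-sided p-values use a standard normal reference by default (an optional
Student-t reference is available for small samples) and are adjusted by
the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bias import BiasCorrection, debias, mci
from .data import AbundanceTable, CovariateSet
from .io import prevalence_filter
from .model import EMControl, EMFit, fit_em

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "taxon",
    "delta_tilde",
    "delta_hat",
    "se",
    "t",
    "pvalue",
    "qvalue",
    "significant",
]


def modified_t(Delta_hat, se_tilde, var_gamma):
    """Wald-type statistic with the bias-estimation variance added in."""
    Delta_hat = np.asarray(Delta_hat, dtype=float)
    se_tilde = np.asarray(se_tilde, dtype=float)
    var_gamma = np.asarray(var_gamma, dtype=float)
    if np.any(se_tilde[np.isfinite(se_tilde)] <= 0):
        raise ValueError("se_tilde must be positive")
    if np.any(var_gamma < 0):
        raise ValueError("var_gamma must be non-negative")
    out = Delta_hat / np.sqrt(se_tilde**2 + var_gamma)
    return out if out.ndim else float(out)


def p_value(t, reference: str = "normal", df: float | None = None):
    """Two-sided tail probability of the test statistic.

    ``reference`` is ``"normal"`` (default) or ``"t"`` with ``df`` degrees
    of freedom.  Non-finite statistics yield NaN with a warning.
    """
    t = np.asarray(t, dtype=float)
    bad = ~np.isfinite(t)
    if np.any(bad):
        warnings.warn("non-finite test statistic; returning NaN p-value", stacklevel=2)
    if reference == "normal":
        p = 2.0 * stats.norm.sf(np.abs(t))
    elif reference == "t":
        if df is None or df <= 0:
            raise ValueError("t reference requires positive df")
        p = 2.0 * stats.t.sf(np.abs(t), df=df)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    p = np.where(bad, np.nan, p)
    return p if p.ndim else float(p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaN entries (untested hypotheses) are excluded from the correction —
    they do not enter the number of tests — and returned as NaN.
    """
    p = np.asarray(p, dtype=float).ravel()
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if np.any(ok):
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class PipelineSettings:
    """Settings for the full testing pipeline."""

    rho: float = 0.5
    fdr_level: float = 0.05
    prevalence_min: float = 0.05
    reference: str = "normal"  # or "t"
    em: EMControl = field(default_factory=EMControl)


@dataclass
class DAResultSet:
    """Per-taxon test results plus shared run metadata."""

    table: pd.DataFrame  # columns RESULT_COLUMNS (+ estimable)
    bias: BiasCorrection
    fit: EMFit
    settings: PipelineSettings
    dropped_taxa: list[str] = field(default_factory=list)


def run_mbdecoda(
    table: AbundanceTable,
    cov: CovariateSet,
    settings: PipelineSettings | None = None,
) -> DAResultSet:
    """Full pipeline: prevalence filter, ZINB-EM fit, MCI bias correction,
    modified t-test and BH adjustment.

    Returns one row per retained taxon; taxa flagged non-estimable carry
    NaN statistics and are excluded from the multiplicity correction.
    """
    settings = settings or PipelineSettings()
    filtered, dropped = prevalence_filter(table, settings.prevalence_min)
    if dropped:
        logger.info("prevalence filter dropped %d taxa", len(dropped))
    if filtered.n_taxa == 0:
        raise ValueError("no taxa pass the prevalence filter")

    fit = fit_em(filtered, cov, control=settings.em)
    Delta_tilde = fit.params.Delta
    bc = mci(Delta_tilde, rho=settings.rho)
    Delta_hat = debias(Delta_tilde, bc)

    se = fit.se_Delta_tilde
    with np.errstate(invalid="ignore"):
        t = Delta_hat / np.sqrt(se**2 + bc.var_gamma_hat)
    df = filtered.n_samples - cov.V.shape[1] - 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = p_value(t, reference=settings.reference, df=df)
    q = bh_adjust(p)
    significant = np.where(np.isfinite(q), q <= settings.fdr_level, False)

    df_out = pd.DataFrame(
        {
            "taxon": fit.taxon_ids,
            "delta_tilde": Delta_tilde,
            "delta_hat": Delta_hat,
            "se": se,
            "t": t,
            "pvalue": p,
            "qvalue": q,
            "significant": significant.astype(bool),
        }
    )
    df_out["estimable"] = fit.estimable
    return DAResultSet(
        table=df_out, bias=bc, fit=fit, settings=settings, dropped_taxa=dropped
    )
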