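"""Zero-inflated negative binomial model and its EM fitter.

Each count ``Y_ik`` is modelled as a two-component mixture: with probability
``eta_ik`` the taxon is structurally absent (a point mass at zero) and
otherwise the count is negative binomial with mean ``mu_ik`` and dispersion
``phi_k``::

    logit(eta_ik) = U_i' alpha_k
    log(mu_ik)    = d_i + X_i * Delta_k + V_i' beta_k

``d_i`` is a sample-specific compositional offset absorbing the unknown
sampling fraction, and ``Delta_k`` is the log fold change of taxon ``k`` per
unit of the variable of interest.  Because ``d_i`` and ``Delta_k`` are
confounded along ``X``, the EM estimate ``Delta_tilde`` carries a common
additive bias; estimating and removing that bias is the job of
:mod:`mbdecoda.bias`.

The EM alternates an exact E-step (posterior probability that each observed
zero is structural) with block maximizations: a fractional-response logistic
regression for ``alpha`` and a weighted negative binomial regression for
``(d, Delta, beta, phi)``, the latter split into taxon-wise and sample-wise
coordinate ascents.  All block updates are ascent steps, so the marginal
log-likelihood is non-decreasing along the trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, polygamma, xlogy

from .data import AbundanceTable, CovariateSet

logger = logging.getLogger(__name__)

# linear predictors are clipped here before exponentiation; counts in
# realistic tables keep log-means far inside this range
_PSI_CLIP = 50.0
_ETA_CLIP = 1e-6
_PHI_BOUNDS = (1e-3, 1e6)


class ModelError(ValueError):
    """Raised on invalid model inputs or unidentifiable fits."""


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------


def nb_logpmf(y, mu, phi):
    """Log-pmf of the negative binomial in mean/dispersion form.

    ``p(y | mu, phi) = Gamma(y+phi)/(Gamma(phi) y!) (phi/(mu+phi))^phi
    (mu/(mu+phi))^y``.  Evaluated entirely on the log scale; broadcasting
    over array arguments is supported.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu <= 0) or not np.all(np.isfinite(mu)):
        raise ModelError("mu must be positive and finite")
    if np.any(phi <= 0) or not np.all(np.isfinite(phi)):
        raise ModelError("phi must be positive and finite")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ModelError("y must be a non-negative integer")
    y = y.astype(float)
    out = (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1.0)
        + xlogy(phi, phi / (mu + phi))
        + xlogy(y, mu / (mu + phi))
    )
    return out if out.ndim else float(out)


def _nb_logpmf_raw(y, mu, phi):
    """Unchecked vectorized NB log-pmf (internal hot path)."""
    return (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1.0)
        + xlogy(phi, phi / (mu + phi))
        + xlogy(y, mu / (mu + phi))
    )


def _eta_mu(cov: CovariateSet, params: "ZINBParams"):
    """Linear predictors -> (eta, mu), each n x K."""
    lin_eta = cov.U @ params.alpha.T
    eta = 1.0 / (1.0 + np.exp(-np.clip(lin_eta, -_PSI_CLIP, _PSI_CLIP)))
    psi = (
        params.d[:, None]
        + cov.X[:, None] * params.Delta[None, :]
        + cov.V @ params.beta.T
    )
    mu = np.exp(np.clip(psi, -_PSI_CLIP, _PSI_CLIP))
    return eta, mu


def _marginal_loglik_arrays(y, eta, mu, phi):
    """Sum of log[eta 1{y=0} + (1-eta) NB(y)] with log-sum-exp stability."""
    lognb = _nb_logpmf_raw(y.astype(float), mu, phi[None, :])
    with np.errstate(divide="ignore"):
        log_eta = np.log(eta)
        log_1meta = np.log1p(-eta)
    # y > 0: only the NB branch contributes
    terms = log_1meta + lognb
    zero = y == 0
    if np.any(zero):
        mix = np.logaddexp(log_eta, log_1meta + lognb)
        terms = np.where(zero, mix, terms)
    return float(terms.sum())


def zinb_marginal_loglik(
    table: AbundanceTable, cov: CovariateSet, params: "ZINBParams"
) -> float:
    """Marginal (incomplete-data) log-likelihood of the ZINB model."""
    _check_dims(table, cov, params)
    eta, mu = _eta_mu(cov, params)
    return _marginal_loglik_arrays(table.counts, eta, mu, params.phi)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ZINBParams:
    """Full parameter set Theta = {d, Delta, beta, alpha, phi}."""

    d: np.ndarray  # (n,) sample offsets
    Delta: np.ndarray  # (K,) log fold changes
    beta: np.ndarray  # (K, p2+1) abundance coefficients, col 0 = intercept
    alpha: np.ndarray  # (K, p1+1) zero-model coefficients
    phi: np.ndarray  # (K,) dispersions

    def copy(self) -> "ZINBParams":
        return ZINBParams(
            self.d.copy(),
            self.Delta.copy(),
            self.beta.copy(),
            self.alpha.copy(),
            self.phi.copy(),
        )


@dataclass
class EMControl:
    """Convergence settings for the EM fitter.

    ``tol`` is on the relative change of the marginal log-likelihood,
    ``inner_tol`` on the per-taxon weighted NB objective; ``n_alternations``
    bounds the taxa/sample coordinate passes inside one outer M-step.
    """

    tol: float = 1e-6
    max_iter: int = 100
    inner_tol: float = 1e-8
    inner_max_iter: int = 50
    n_alternations: int = 3
    phi_bounds: tuple[float, float] = _PHI_BOUNDS


@dataclass
class EMFit:
    """Result of the EM run, aligned to the retained (non-all-zero) taxa."""

    params: ZINBParams
    posterior: np.ndarray  # (n, K) structural-zero posterior; NaN if non-estimable
    se_Delta_tilde: np.ndarray  # (K,) standard errors of Delta_tilde
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    taxa_converged: np.ndarray | None = None
    estimable: np.ndarray | None = None
    taxon_ids: list[str] = field(default_factory=list)

    @property
    def Delta_tilde(self) -> np.ndarray:
        return self.params.Delta


def _check_dims(table: AbundanceTable, cov: CovariateSet, params: ZINBParams) -> None:
    n, K = table.counts.shape
    if cov.n_samples != n:
        raise ModelError("covariate rows do not match the count table")
    if (
        params.d.shape != (n,)
        or params.Delta.shape != (K,)
        or params.phi.shape != (K,)
        or params.beta.shape != (K, cov.V.shape[1])
        or params.alpha.shape != (K, cov.U.shape[1])
    ):
        raise ModelError("parameter dimensions do not match table/covariates")


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------


def e_step(table: AbundanceTable, cov: CovariateSet, params: ZINBParams) -> np.ndarray:
    """Posterior probability that each observed zero is structural.

    For ``Y_ik = 0``: ``z = eta / (eta + (1-eta) (phi/(mu+phi))^phi)``;
    exactly 0 wherever ``Y_ik > 0``.
    """
    _check_dims(table, cov, params)
    eta, mu = _eta_mu(cov, params)
    return _e_step_arrays(table.counts, eta, mu, params.phi)


def _e_step_arrays(y, eta, mu, phi):
    log_p0 = xlogy(phi[None, :], phi[None, :] / (mu + phi[None, :]))
    z = eta / (eta + (1.0 - eta) * np.exp(log_p0))
    z = np.where(y == 0, z, 0.0)
    return z


# ---------------------------------------------------------------------------
# M-step: zero model (fractional-response logistic regression)
# ---------------------------------------------------------------------------


def m_step_zero(posterior: np.ndarray, cov: CovariateSet, alpha0=None) -> np.ndarray:
    """Maximize Q1: taxon-wise logistic regression with fractional responses.

    Returns the ``K x (p1+1)`` coefficient matrix.  Taxa whose posteriors
    are all essentially zero skip the fit and receive the clamped intercept
    ``logit(1e-6)``; fitted probabilities are clamped to
    ``[1e-6, 1 - 1e-6]`` throughout, which keeps separated taxa finite.
    """
    z = np.asarray(posterior, dtype=float)
    if np.any(z < 0) or np.any(z > 1):
        raise ModelError("posterior entries must lie in [0, 1]")
    U = cov.U
    n, K = z.shape
    p = U.shape[1]
    alpha = np.zeros((K, p)) if alpha0 is None else np.array(alpha0, dtype=float)

    zbar = z.mean(axis=0)
    degenerate = zbar < 1e-4
    lo = np.log(_ETA_CLIP / (1.0 - _ETA_CLIP))

    if p == 1:
        # intercept-only: closed form logit of the clamped mean
        c = np.clip(zbar, _ETA_CLIP, 1.0 - _ETA_CLIP)
        alpha = np.log(c / (1.0 - c))[:, None]
        alpha[degenerate, 0] = lo
        return alpha

    active = ~degenerate
    alpha[degenerate] = 0.0
    alpha[degenerate, 0] = lo
    if not np.any(active):
        return alpha

    za = z[:, active]
    a = alpha[active]

    def objective(a_):
        eta = 1.0 / (1.0 + np.exp(-np.clip(U @ a_.T, -_PSI_CLIP, _PSI_CLIP)))
        eta = np.clip(eta, _ETA_CLIP, 1.0 - _ETA_CLIP)
        return (xlogy(za, eta) + xlogy(1.0 - za, 1.0 - eta)).sum(axis=0)

    obj = objective(a)
    for _ in range(50):
        eta = 1.0 / (1.0 + np.exp(-np.clip(U @ a.T, -_PSI_CLIP, _PSI_CLIP)))
        eta = np.clip(eta, _ETA_CLIP, 1.0 - _ETA_CLIP)
        g = np.einsum("ip,ik->kp", U, za - eta)
        w = eta * (1.0 - eta)
        A = np.einsum("ip,ik,iq->kpq", U, w, U)
        A += 1e-10 * np.eye(p)[None, :, :]
        step = np.linalg.solve(A, g[..., None])[..., 0]
        a_new, obj_new = _halving(a, step, obj, objective)
        if np.max(np.abs(obj_new - obj) / (np.abs(obj) + 1.0)) < 1e-10:
            a, obj = a_new, obj_new
            break
        a, obj = a_new, obj_new
    alpha[active] = np.clip(a, -_PSI_CLIP, _PSI_CLIP)
    return alpha


def _halving(x, step, obj, objective, max_halve=25):
    """Backtracking line search applied independently per taxon/sample."""
    scale = np.ones(x.shape[0])
    x_new = x + step * (scale[:, None] if x.ndim == 2 else scale)
    obj_new = objective(x_new)
    for _ in range(max_halve):
        worse = obj_new < obj - 1e-12
        if not np.any(worse):
            break
        scale[worse] *= 0.5
        x_new = x + step * (scale[:, None] if x.ndim == 2 else scale)
        obj_new = objective(x_new)
    worse = obj_new < obj
    if np.any(worse):
        if x.ndim == 2:
            x_new[worse] = x[worse]
        else:
            x_new = np.where(worse, x, x_new)
        obj_new = np.where(worse, obj, obj_new)
    return x_new, obj_new


# ---------------------------------------------------------------------------
# M-step: weighted NB regression, taxon-wise coefficients and dispersion
# ---------------------------------------------------------------------------


def _weighted_nb_loglik(y, W, offset, weights, theta, phi):
    psi = offset + W @ theta.T
    mu = np.exp(np.clip(psi, -_PSI_CLIP, _PSI_CLIP))
    return (weights * _nb_logpmf_raw(y, mu, phi[None, :])).sum(axis=0)


def m_step_nb_taxa(
    table: AbundanceTable,
    cov: CovariateSet,
    posterior: np.ndarray,
    d: np.ndarray,
    Delta0: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    phi0: np.ndarray | None = None,
    control: EMControl | None = None,
):
    """Maximize Q2 over (Delta, beta, phi) with the sample offsets fixed.

    For each taxon this is a weighted NB regression of the counts on
    ``[X, V]`` with offset ``d`` and weights ``1 - z``; coefficients are
    updated by Fisher scoring and the dispersion by a safeguarded Newton
    profile search on ``log(phi)``.  All taxa are updated simultaneously
    with batched linear algebra.

    Returns ``(Delta, beta, phi, converged_per_taxon)``.
    """
    control = control or EMControl()
    y = table.counts.astype(float)
    n, K = y.shape
    weights = 1.0 - np.asarray(posterior, dtype=float)
    wsum_pos = (weights * (y > 0)).sum(axis=0)
    if np.any(wsum_pos <= 1e-8):
        raise ModelError(
            "taxon with no effectively observed counts; drop non-estimable "
            "taxa before the weighted NB fit"
        )
    W = np.column_stack([cov.X, cov.V])  # coefficient order: Delta, beta
    p = W.shape[1]
    theta = np.zeros((K, p))
    if Delta0 is not None:
        theta[:, 0] = Delta0
    if beta0 is not None:
        theta[:, 1:] = beta0
    else:
        theta[:, 1] = np.log(np.maximum(y.mean(axis=0), 1e-8)) - np.mean(d)
    phi = np.ones(K) if phi0 is None else np.array(phi0, dtype=float)
    offset = d[:, None]

    def coef_objective(th):
        return _weighted_nb_loglik(y, W, offset, weights, th, phi)

    obj = coef_objective(theta)
    converged = np.zeros(K, dtype=bool)
    for _ in range(control.inner_max_iter):
        # Fisher scoring pass on the coefficients
        psi = offset + W @ theta.T
        mu = np.exp(np.clip(psi, -_PSI_CLIP, _PSI_CLIP))
        r = weights * (y - mu) * phi[None, :] / (mu + phi[None, :])
        fw = weights * phi[None, :] * mu / (mu + phi[None, :])
        A = np.einsum("ip,ik,iq->kpq", W, fw, W)
        A += 1e-10 * np.eye(p)[None, :, :]
        g = np.einsum("ip,ik->kp", W, r)
        step = np.linalg.solve(A, g[..., None])[..., 0]
        theta, obj_c = _halving(theta, step, obj, coef_objective)

        # profile update of the dispersion
        psi = offset + W @ theta.T
        mu = np.exp(np.clip(psi, -_PSI_CLIP, _PSI_CLIP))
        phi, obj_new = _profile_phi(y, mu, weights, phi, control)

        rel = np.abs(obj_new - obj) / (np.abs(obj) + 1.0)
        converged = rel < control.inner_tol
        obj = obj_new
        if np.all(converged):
            break
    return theta[:, 0], theta[:, 1:], phi, converged


def _profile_phi(y, mu, weights, phi, control, n_newton=25):
    """Safeguarded Newton maximization of the weighted NB profile in log(phi)."""
    lo, hi = control.phi_bounds
    t = np.log(phi)

    def objective(t_):
        return (weights * _nb_logpmf_raw(y, mu, np.exp(t_)[None, :])).sum(axis=0)

    obj = objective(t)
    for _ in range(n_newton):
        ph = np.exp(t)[None, :]
        d1 = (
            weights
            * (
                digamma(y + ph)
                - digamma(ph)
                + np.log(ph)
                + 1.0
                - np.log(mu + ph)
                - (ph + y) / (mu + ph)
            )
        ).sum(axis=0)
        d2 = (
            weights
            * (
                polygamma(1, y + ph)
                - polygamma(1, ph)
                + 1.0 / ph
                - 1.0 / (mu + ph)
                - (mu - y) / (mu + ph) ** 2
            )
        ).sum(axis=0)
        phv = np.exp(t)
        gt = phv * d1
        ht = phv * d1 + phv**2 * d2
        step = np.where(ht < -1e-12, -gt / ht, np.sign(gt) * 0.5)
        step = np.clip(step, -2.0, 2.0)

        def clipped_objective(t_):
            return objective(np.clip(t_, np.log(lo), np.log(hi)))

        t_new, obj_new = _halving(t, step, obj, clipped_objective)
        t_new = np.clip(t_new, np.log(lo), np.log(hi))
        if np.max(np.abs(obj_new - obj) / (np.abs(obj) + 1.0)) < 1e-12:
            t, obj = t_new, obj_new
            break
        t, obj = t_new, obj_new
    phi = np.exp(t)
    if np.any(phi >= hi * 0.999):
        logger.debug(
            "%d taxa hit the dispersion upper bound (effectively Poisson)",
            int(np.sum(phi >= hi * 0.999)),
        )
    return phi, obj


def m_step_nb_samples(
    table: AbundanceTable,
    cov: CovariateSet,
    posterior: np.ndarray,
    Delta: np.ndarray,
    beta: np.ndarray,
    phi: np.ndarray,
    d0: np.ndarray | None = None,
    n_newton: int = 30,
) -> np.ndarray:
    """Maximize Q2 over the sample offsets ``d`` with taxa parameters fixed.

    Each ``d_i`` solves an independent one-dimensional concave problem;
    all samples are updated together by damped Newton.  The returned vector
    is NOT re-centered — the caller owns the centering convention.
    """
    y = table.counts.astype(float)
    n, K = y.shape
    weights = 1.0 - np.asarray(posterior, dtype=float)
    if np.any(weights.sum(axis=1) <= 1e-8):
        i = int(np.argmin(weights.sum(axis=1)))
        raise ModelError(f"sample index {i} carries no NB information (all weights ~0)")
    off = cov.X[:, None] * Delta[None, :] + cov.V @ beta.T  # n x K
    d = np.log(np.maximum(y.sum(axis=1), 1.0)) if d0 is None else np.array(d0, float)

    def objective(d_):
        mu = np.exp(np.clip(d_[:, None] + off, -_PSI_CLIP, _PSI_CLIP))
        return (weights * _nb_logpmf_raw(y, mu, phi[None, :])).sum(axis=1)

    obj = objective(d)
    for _ in range(n_newton):
        mu = np.exp(np.clip(d[:, None] + off, -_PSI_CLIP, _PSI_CLIP))
        g = (weights * (y - mu) * phi[None, :] / (mu + phi[None, :])).sum(axis=1)
        h = -(
            weights * phi[None, :] * mu * (phi[None, :] + y) / (mu + phi[None, :]) ** 2
        ).sum(axis=1)
        step = np.where(h < -1e-12, -g / h, np.sign(g))
        step = np.clip(step, -5.0, 5.0)
        d, obj_new = _halving(d, step, obj, objective)
        if np.max(np.abs(obj_new - obj) / (np.abs(obj) + 1.0)) < 1e-12:
            obj = obj_new
            break
        obj = obj_new
    return d


# ---------------------------------------------------------------------------
# full EM
# ---------------------------------------------------------------------------


def _init_params(table, cov, control, d_fixed=None):
    """Starting values: library-size offsets, Poisson-style coefficient fits."""
    y = table.counts.astype(float)
    n, K = y.shape
    if d_fixed is None:
        d = np.log(y.sum(axis=1))
        d -= d.mean()
    else:
        d = np.asarray(d_fixed, dtype=float).copy()
    # beta: Poisson regression of each taxon on V with offset d (Delta = 0);
    # a few Fisher-scoring steps are enough for a starting value
    V = cov.V
    p2 = V.shape[1]
    beta = np.zeros((K, p2))
    beta[:, 0] = np.log(np.maximum((y / np.exp(d)[:, None]).mean(axis=0), 1e-8))
    ones = np.ones_like(y)
    big_phi = np.full(K, 1e8)

    def pois_obj(b):
        return _weighted_nb_loglik(y, V, d[:, None], ones, b, big_phi)

    obj = pois_obj(beta)
    for _ in range(25):
        mu = np.exp(np.clip(d[:, None] + V @ beta.T, -_PSI_CLIP, _PSI_CLIP))
        g = np.einsum("ip,ik->kp", V, y - mu)
        A = np.einsum("ip,ik,iq->kpq", V, mu, V) + 1e-8 * np.eye(p2)[None]
        step = np.linalg.solve(A, g[..., None])[..., 0]
        beta, obj_new = _halving(beta, step, obj, pois_obj)
        if np.max(np.abs(obj_new - obj) / (np.abs(obj) + 1.0)) < 1e-9:
            obj = obj_new
            break
        obj = obj_new
    alpha = m_step_zero((y == 0).astype(float), cov)
    return ZINBParams(
        d=d,
        Delta=np.zeros(K),
        beta=beta,
        alpha=alpha,
        phi=np.ones(K),
    )


def _se_delta(table, cov, posterior, params):
    """SE(Delta_tilde) from the observed information of the final weighted
    NB regression, with posteriors and sample offsets held fixed."""
    y = table.counts.astype(float)
    weights = 1.0 - posterior
    W = np.column_stack([cov.X, cov.V])
    p = W.shape[1]
    _, mu = _eta_mu(cov, params)
    phi = params.phi[None, :]
    c = weights * phi * mu * (phi + y) / (mu + phi) ** 2
    H = np.einsum("ip,ik,iq->kpq", W, c, W) + 1e-12 * np.eye(p)[None]
    cov_theta = np.linalg.inv(H)
    var = cov_theta[:, 0, 0]
    return np.sqrt(np.maximum(var, 0.0))


def fit_em(
    table: AbundanceTable,
    cov: CovariateSet,
    control: EMControl | None = None,
    d_fixed: np.ndarray | None = None,
) -> EMFit:
    """Fit the ZINB model by EM and return biased effect estimates.

    All-zero taxa are excluded before fitting (with a warning); taxa with
    fewer than two non-zero samples are retained in the output but flagged
    non-estimable and carry NaN statistics.  The returned ``Delta_tilde``
    estimates share a common unknown compositional bias.

    ``d_fixed`` holds the sample offsets at known values (no sample-wise
    update, no recentering) — useful when the sampling fractions are known,
    e.g. in validation against a direct likelihood maximization.
    """
    control = control or EMControl()
    if table.n_samples != cov.n_samples:
        raise ModelError("covariate rows do not match the count table")

    nonzero = (table.counts > 0).sum(axis=0)
    if np.any(nonzero == 0):
        dropped = [t for t, nz in zip(table.taxon_ids, nonzero) if nz == 0]
        logger.warning("excluding %d all-zero taxa: %s", len(dropped), dropped[:10])
        table = table.select_taxa(nonzero > 0)
        nonzero = nonzero[nonzero > 0]
    n, K = table.counts.shape
    if K == 0:
        raise ModelError("no taxa left to fit")

    estimable = nonzero >= 2
    if not np.any(estimable):
        raise ModelError("no estimable taxa (all are non-zero in < 2 samples)")
    if not np.all(estimable):
        logger.warning(
            "%d taxa are non-zero in < 2 samples; flagged non-estimable",
            int(np.sum(~estimable)),
        )
    sub = table.select_taxa(estimable)
    y = sub.counts
    Ke = y.shape[1]

    if d_fixed is not None and np.asarray(d_fixed).shape != (n,):
        raise ModelError("d_fixed must have one entry per sample")
    params = _init_params(sub, cov, control, d_fixed=d_fixed)
    eta, mu = _eta_mu(cov, params)
    trace = [_marginal_loglik_arrays(y, eta, mu, params.phi)]
    converged = False
    taxa_conv = np.zeros(Ke, dtype=bool)
    it = 0
    for it in range(1, control.max_iter + 1):
        z = _e_step_arrays(y, eta, mu, params.phi)
        params.alpha = m_step_zero(z, cov, alpha0=params.alpha)

        q2_prev = None
        for _ in range(control.n_alternations):
            params.Delta, params.beta, params.phi, taxa_conv = m_step_nb_taxa(
                sub, cov, z, params.d,
                Delta0=params.Delta, beta0=params.beta, phi0=params.phi,
                control=control,
            )
            if d_fixed is None:
                params.d = m_step_nb_samples(
                    sub, cov, z, params.Delta, params.beta, params.phi, d0=params.d
                )
                # identifiability: recenter d, absorb the shift into intercepts
                shift = params.d.mean()
                params.d -= shift
                params.beta[:, 0] += shift
            q2 = _weighted_nb_loglik(
                y.astype(float),
                np.column_stack([cov.X, cov.V]),
                params.d[:, None],
                1.0 - z,
                np.column_stack([params.Delta, params.beta]),
                params.phi,
            ).sum()
            if q2_prev is not None and abs(q2 - q2_prev) / (abs(q2) + 1.0) < control.inner_tol:
                q2_prev = q2
                break
            q2_prev = q2

        eta, mu = _eta_mu(cov, params)
        ll = _marginal_loglik_arrays(y, eta, mu, params.phi)
        trace.append(ll)
        if abs(ll - trace[-2]) / (abs(ll) + 1.0) < control.tol:
            converged = True
            break

    z = _e_step_arrays(y, eta, mu, params.phi)
    se = _se_delta(sub, cov, z, params)

    # scatter the estimable-taxon results back to the retained-taxon axis
    full = ZINBParams(
        d=params.d,
        Delta=np.full(K, np.nan),
        beta=np.full((K, cov.V.shape[1]), np.nan),
        alpha=np.full((K, cov.U.shape[1]), np.nan),
        phi=np.full(K, np.nan),
    )
    idx = np.flatnonzero(estimable)
    full.Delta[idx] = params.Delta
    full.beta[idx] = params.beta
    full.alpha[idx] = params.alpha
    full.phi[idx] = params.phi
    posterior = np.full((n, K), np.nan)
    posterior[:, idx] = z
    se_full = np.full(K, np.nan)
    se_full[idx] = se

    taxa_conv_full = np.zeros(K, dtype=bool)
    taxa_conv_full[idx] = taxa_conv
    return EMFit(
        params=full,
        posterior=posterior,
        se_Delta_tilde=se_full,
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
        taxa_converged=taxa_conv_full,
        estimable=estimable,
        taxon_ids=list(table.taxon_ids),
    )
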