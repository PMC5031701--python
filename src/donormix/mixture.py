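"""Constrained three-component Gaussian mixture for donor-signal fractions.

The per-locus minor-allele fractions at recipient-homozygous loci arise
from three biological classes of donor genotype, with Hardy-Weinberg
proportions 1:2:1 at evenly biallelic loci:

* both donor alleles shared with the recipient — signal is pure
  base-calling error, mean ``mu_err``;
* one shared allele (OSA) — donor contributes half its reads to the
  minor allele, mean ``mu_osa`` ~ x/2;
* no shared allele (NSA) — mean ``mu_nsa`` ~ x, the donor fraction.

The mixture is fit by EM with three linear constraints that make the
small-sample fit identifiable: mixing weights are *fixed* at
(0.25, 0.5, 0.25), and the OSA:NSA means and standard deviations are
tied at a 1:2 ratio (``mu_nsa = 2 mu_osa``, ``sigma_nsa = 2 sigma_osa``).
The M-step solves the responsibility-weighted least-squares problem
under these equalities in closed form, so the EM ascent property is
preserved exactly. The donor-fraction estimate from one fit is
``mu_nsa - mu_err`` (clamped at zero).

The 1:2 mean constraint is exact only when the error rate is small
relative to the donor fraction (physically OSA ~ x/2 + e-scale terms and
NSA ~ x); it is enforced as a modelling choice that stabilises fits in
the regime the assay targets (x well below 14%, e ~ 0.1%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils import check_array, check_random_state

from .exceptions import DonorMixError, InsufficientDataError

#: Fixed mixing weights: both-shared (error) : OSA : NSA = 1:2:1.
MIXTURE_WEIGHTS = (0.25, 0.50, 0.25)

#: Initial error-component mean: the theoretical Q30 error rate (0.1%).
DEFAULT_MU_ERR_INIT = 0.001

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 500
DEFAULT_VARIANCE_FLOOR = 1e-5  # sigma floor, fraction units

MIN_FRACTIONS = 6

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class MixtureFitResult:
    """Parameters of one converged (or stopped) constrained mixture fit."""

    mu_err: float
    mu_osa: float
    mu_nsa: float
    sigma_err: float
    sigma_osa: float
    sigma_nsa: float
    weights: tuple = MIXTURE_WEIGHTS
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    loglik_path: tuple = field(default=(), repr=False)

    @property
    def donor_fraction(self) -> float:
        """Per-fit donor-fraction estimate: NSA mean minus the error mean."""
        return max(0.0, self.mu_nsa - self.mu_err)

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mu_err, self.mu_osa, self.mu_nsa])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_err, self.sigma_osa, self.sigma_nsa])


def _component_logpdf(x: np.ndarray, means: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """(n, 3) matrix of component log-densities."""
    z = (x[:, None] - means[None, :]) / sigmas[None, :]
    return -0.5 * z * z - np.log(sigmas)[None, :] - _LOG_SQRT_2PI


def _em_constrained(
    x: np.ndarray,
    mu_err: float,
    mu_osa: float,
    sigma_err: float,
    sigma_osa: float,
    tol: float,
    max_iter: int,
    variance_floor: float,
) -> MixtureFitResult:
    """Run constrained EM from a single starting point.

    Closed-form M-step under mu_nsa = 2 mu_osa, sigma_nsa = 2 sigma_osa:

        mu_err   = sum(r1 x) / sum(r1)
        mu_osa   = (sum(r2 x) + sum(r3 x)/2) / (sum(r2) + sum(r3))
        sigma_o² = (sum(r2 (x-mu_o)²) + sum(r3 (x-2mu_o)²)/4) / (sum(r2)+sum(r3))

    Sigmas are floored at ``variance_floor``; since the floored value is
    the constrained maximizer of the M-step objective, the EM ascent
    property still holds with the floor active.
    """
    log_w = np.log(np.asarray(MIXTURE_WEIGHTS))
    sigma_err = max(sigma_err, variance_floor)
    sigma_osa = max(sigma_osa, variance_floor)
    prev_ll = -np.inf
    path: list[float] = []
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        means = np.array([mu_err, mu_osa, 2.0 * mu_osa])
        sigmas = np.array([sigma_err, sigma_osa, 2.0 * sigma_osa])
        log_joint = _component_logpdf(x, means, sigmas) + log_w[None, :]
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        path.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll

        resp = np.exp(log_joint - log_norm[:, None])  # (n, 3)
        r1, r2, r3 = resp[:, 0], resp[:, 1], resp[:, 2]
        n1 = max(r1.sum(), 1e-300)
        n23 = max(r2.sum() + r3.sum(), 1e-300)

        mu_err = float((r1 @ x) / n1)
        mu_osa = float(((r2 @ x) + 0.5 * (r3 @ x)) / n23)
        var_err = float(r1 @ (x - mu_err) ** 2 / n1)
        var_osa = float((r2 @ (x - mu_osa) ** 2 + 0.25 * (r3 @ (x - 2.0 * mu_osa) ** 2)) / n23)
        sigma_err = max(math.sqrt(max(var_err, 0.0)), variance_floor)
        sigma_osa = max(math.sqrt(max(var_osa, 0.0)), variance_floor)

    return MixtureFitResult(
        mu_err=mu_err,
        mu_osa=mu_osa,
        mu_nsa=2.0 * mu_osa,
        sigma_err=sigma_err,
        sigma_osa=sigma_osa,
        sigma_nsa=2.0 * sigma_osa,
        loglik=path[-1],
        n_iter=n_iter,
        converged=converged,
        loglik_path=tuple(path),
    )


def _validate_fractions(fractions) -> np.ndarray:
    x = np.asarray(fractions, dtype=float).ravel()
    if x.size < MIN_FRACTIONS:
        raise InsufficientDataError(
            f"need at least {MIN_FRACTIONS} locus fractions to fit the mixture, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise DonorMixError("non-finite values in locus fractions")
    if np.any((x < 0) | (x > 1)):
        raise DonorMixError("locus fractions must lie in [0, 1]")
    return x


def default_init(x: np.ndarray, variance_floor: float = DEFAULT_VARIANCE_FLOOR):
    """Deterministic starting point: error mean at the Q30 rate, OSA mean
    at the sample median (the 50%-weight component), sigmas at half the means."""
    mu_err = DEFAULT_MU_ERR_INIT
    mu_osa = max(float(np.median(x)), 10.0 * variance_floor)
    return mu_err, mu_osa, mu_err / 2.0, mu_osa / 2.0


class ConstrainedGaussianMixture(DensityMixin, BaseEstimator):
    """Three-component Gaussian mixture with fixed 1:2:1 weights and tied
    OSA:NSA mean/SD ratios, fit by EM.

    A deterministic, single-start density estimator in the scikit-learn
    style; random multi-start aggregation lives in
    :class:`~donormix.estimator.DonorFractionEstimator`.

    Parameters
    ----------
    tol : float
        EM stops when the log-likelihood improvement drops below this.
    max_iter : int
        Maximum EM iterations.
    variance_floor : float
        Lower bound on component standard deviations (fraction units);
        prevents degenerate spikes on near-constant data.
    mean_init : tuple (mu_err, mu_osa) or None
        Starting means; None uses :func:`default_init`.
    sigma_init : tuple (sigma_err, sigma_osa) or None
        Starting SDs; None uses half the starting means.

    Attributes
    ----------
    means_ : ndarray (3,), sigmas_ : ndarray (3,), weights_ : ndarray (3,)
        Fitted component parameters (error, OSA, NSA); the constraints
        ``means_[2] == 2 * means_[1]`` and ``sigmas_[2] == 2 * sigmas_[1]``
        hold exactly.
    loglik_ : float, n_iter_ : int, converged_ : bool
    result_ : MixtureFitResult
    """

    def __init__(
        self,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        variance_floor: float = DEFAULT_VARIANCE_FLOOR,
        mean_init=None,
        sigma_init=None,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.variance_floor = variance_floor
        self.mean_init = mean_init
        self.sigma_init = sigma_init

    def _as_fractions(self, X) -> np.ndarray:
        X = check_array(X, ensure_2d=False, dtype=float, ensure_all_finite=False)
        if X.ndim == 2 and X.shape[1] != 1:
            raise DonorMixError("expected a single feature (locus fractions)")
        return _validate_fractions(X)

    def fit(self, X, y=None):
        """Fit the constrained mixture to per-locus minor-allele fractions."""
        if self.tol <= 0:
            raise DonorMixError("tol must be positive")
        x = self._as_fractions(X)
        if self.mean_init is not None:
            mu_err, mu_osa = map(float, self.mean_init)
        else:
            mu_err, mu_osa, *_ = default_init(x, self.variance_floor)
        if self.sigma_init is not None:
            sigma_err, sigma_osa = map(float, self.sigma_init)
        else:
            sigma_err, sigma_osa = mu_err / 2.0, mu_osa / 2.0
        result = _em_constrained(
            x, mu_err, mu_osa, sigma_err, sigma_osa, self.tol, self.max_iter, self.variance_floor
        )
        self.result_ = result
        self.means_ = result.means
        self.sigmas_ = result.sigmas
        self.weights_ = np.asarray(MIXTURE_WEIGHTS)
        self.loglik_ = result.loglik
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.donor_fraction_ = result.donor_fraction
        return self

    def _log_joint(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float).ravel()
        return _component_logpdf(x, self.means_, self.sigmas_) + np.log(self.weights_)[None, :]

    def score_samples(self, X) -> np.ndarray:
        """Per-observation mixture log-density."""
        return logsumexp(self._log_joint(X), axis=1)

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class responsibilities (error, OSA, NSA)."""
        lj = self._log_joint(X)
        return np.exp(lj - logsumexp(lj, axis=1)[:, None])

    def predict(self, X) -> np.ndarray:
        """Most probable signal class per locus (0=error, 1=OSA, 2=NSA)."""
        return np.argmax(self._log_joint(X), axis=1)


def fit_constrained_mixture(
    fractions,
    init=None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> MixtureFitResult:
    """Fit one constrained mixture (thin wrapper over the estimator class).

    ``init`` is ``(mu_err, mu_osa, sigma_err, sigma_osa)`` or None for the
    deterministic default start.
    """
    mean_init = sigma_init = None
    if init is not None:
        mu_err, mu_osa, sigma_err, sigma_osa = init
        mean_init, sigma_init = (mu_err, mu_osa), (sigma_err, sigma_osa)
    est = ConstrainedGaussianMixture(
        tol=tol, max_iter=max_iter, variance_floor=variance_floor,
        mean_init=mean_init, sigma_init=sigma_init,
    ).fit(fractions)
    return est.result_


def mixture_loglikelihood(fractions, params: MixtureFitResult) -> float:
    """Total log-likelihood of ``fractions`` under a fitted parameter set.

    Deterministic; validates the parameter invariants (sigma floor,
    mean/SD ratio constraints, fixed weights).
    """
    if min(params.sigma_err, params.sigma_osa) < DEFAULT_VARIANCE_FLOOR - 1e-15:
        raise DonorMixError("component sigma below the variance floor")
    if not math.isclose(params.mu_nsa, 2.0 * params.mu_osa, rel_tol=1e-12, abs_tol=1e-15):
        raise DonorMixError("mu_nsa must equal 2*mu_osa")
    if not math.isclose(params.sigma_nsa, 2.0 * params.sigma_osa, rel_tol=1e-12):
        raise DonorMixError("sigma_nsa must equal 2*sigma_osa")
    x = np.asarray(fractions, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise DonorMixError("non-finite values in fractions")
    log_joint = _component_logpdf(x, params.means, params.sigmas) + np.log(
        np.asarray(params.weights)
    )
    return float(logsumexp(log_joint, axis=1).sum())


def draw_random_inits(
    x: np.ndarray,
    n: int,
    random_state=None,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> np.ndarray:
    """Draw ``n`` randomized EM starting points, one row per replicate.

    Means are jittered log-uniformly around the deterministic anchors:
    ``mu_err ~ 0.001 * LogUniform(0.5, 2)`` and
    ``mu_osa ~ LogUniform(0.25, 4) * median(x)`` (the OSA component holds
    half the mixture weight, so the sample median anchors it); sigmas
    start at half the corresponding means. Returns an (n, 4) array of
    ``(mu_err, mu_osa, sigma_err, sigma_osa)``.
    """
    rng = check_random_state(random_state) if not isinstance(
        random_state, np.random.Generator
    ) else random_state
    if isinstance(rng, np.random.RandomState):
        uniform = rng.uniform
    else:
        uniform = rng.uniform
    med = max(float(np.median(x)), 10.0 * variance_floor)
    mu_err = DEFAULT_MU_ERR_INIT * np.exp(uniform(math.log(0.5), math.log(2.0), size=n))
    mu_osa = med * np.exp(uniform(math.log(0.25), math.log(4.0), size=n))
    return np.column_stack([mu_err, mu_osa, mu_err / 2.0, mu_osa / 2.0])
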