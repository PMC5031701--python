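"""Replicate-aggregated donor-fraction estimation.

EM on the constrained mixture is sensitive to its starting point, so a
single fit can land in different local optima on different runs. The
estimator therefore repeats the fit from many randomized starting points
(10,000 by default) and reports the mean and SD of the per-replicate
donor-fraction estimates ``max(0, mu_nsa - mu_err)`` on the percent
scale. A bootstrap mode (resampling loci with replacement per replicate)
is available as an alternative source of replicate variation.

A sample is called *detectable* when the mean estimate exceeds the
platform noise floor: the pooled error rate of co-sequenced samples when
available, otherwise a configurable floor defaulting to the theoretical
Q30 error rate (0.1%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import DonorMixError, EstimationError
from .mixture import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    DEFAULT_VARIANCE_FLOOR,
    MixtureFitResult,
    _em_constrained,
    _validate_fractions,
    draw_random_inits,
)
from .selection import SelectedLocus

logger = logging.getLogger(__name__)

DEFAULT_N_REPLICATES = 10_000

#: Default detection floor: theoretical base-call error rate at Q30.
DEFAULT_DETECTION_FLOOR = 0.001


@dataclass(frozen=True)
class DonorEstimate:
    """Replicate-aggregated donor cfDNA percentage for one sample."""

    percent_mean: float
    percent_sd: float
    n_replicates: int
    n_loci_used: int
    detectable: bool
    error_rate_mean: float
    n_nonconverged: int = 0
    pooled_error_rate: float | None = None


class DonorFractionEstimator(BaseEstimator):
    """Estimate the minor-contributor (donor) fraction of a two-person
    DNA mixture from per-locus minor-allele fractions.

    Parameters
    ----------
    n_replicates : int
        Number of randomized EM restarts to aggregate (default 10,000).
    tol, max_iter, variance_floor : float, int, float
        EM controls, passed through to the constrained mixture.
    bootstrap : bool
        If True, each replicate also resamples the loci with replacement.
    detection_floor : float
        Noise floor (fraction units) used for the detectability call when
        no pooled error rate is supplied; defaults to the theoretical Q30
        error rate 0.001.
    pooled_error_rate : float or None
        Across-sample pooled error rate from the same sequencing run; when
        given it replaces ``detection_floor`` as the detectability floor.
    random_state : int, Generator or None
        Seeds the replicate initializations (and bootstrap draws).

    Attributes
    ----------
    percent_mean_, percent_sd_ : float
        Mean and SD of the converged replicate estimates, percent scale.
    n_loci_used_ : int
    n_converged_, n_nonconverged_ : int
    detectable_ : bool
    error_rate_mean_ : float
        Mean fitted error-component mean across converged replicates.
    best_fit_ : MixtureFitResult
        The replicate with the highest log-likelihood.
    replicate_estimates_ : ndarray
        Per-replicate donor-fraction estimates (fraction units).
    """

    def __init__(
        self,
        n_replicates: int = DEFAULT_N_REPLICATES,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        variance_floor: float = DEFAULT_VARIANCE_FLOOR,
        bootstrap: bool = False,
        detection_floor: float = DEFAULT_DETECTION_FLOOR,
        pooled_error_rate: float | None = None,
        random_state=None,
    ):
        self.n_replicates = n_replicates
        self.tol = tol
        self.max_iter = max_iter
        self.variance_floor = variance_floor
        self.bootstrap = bootstrap
        self.detection_floor = detection_floor
        self.pooled_error_rate = pooled_error_rate
        self.random_state = random_state

    def fit(self, X, y=None):
        """Run the replicate EM fits on locus fractions ``X`` (1-D or (n, 1))."""
        if self.n_replicates < 1:
            raise DonorMixError("n_replicates must be >= 1")
        x = _validate_fractions(np.asarray(X, dtype=float))
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        inits = draw_random_inits(x, self.n_replicates, rng, self.variance_floor)

        estimates: list[float] = []
        mu_errs: list[float] = []
        best: MixtureFitResult | None = None
        n_nonconverged = 0
        for rep in range(self.n_replicates):
            data = x if not self.bootstrap else x[rng.integers(0, x.size, size=x.size)]
            fit = _em_constrained(
                data, *inits[rep], self.tol, self.max_iter, self.variance_floor
            )
            if not fit.converged:
                n_nonconverged += 1
                continue
            estimates.append(fit.donor_fraction)
            mu_errs.append(fit.mu_err)
            if best is None or fit.loglik > best.loglik:
                best = fit

        if not estimates:
            raise EstimationError(
                f"no EM replicate converged out of {self.n_replicates} "
                f"(max_iter={self.max_iter}, tol={self.tol}); "
                "inspect the input fractions or raise max_iter"
            )
        if self.n_replicates == 1:
            logger.warning("single replicate: percent_sd_ is 0 by convention")

        est = np.asarray(estimates)
        self.replicate_estimates_ = est
        self.n_loci_used_ = int(x.size)
        self.n_converged_ = int(est.size)
        self.n_nonconverged_ = n_nonconverged
        self.percent_mean_ = float(est.mean() * 100.0)
        self.percent_sd_ = float(est.std(ddof=1) * 100.0) if est.size > 1 else 0.0
        self.error_rate_mean_ = float(np.mean(mu_errs))
        self.best_fit_ = best
        floor = self.pooled_error_rate if self.pooled_error_rate is not None else self.detection_floor
        self.detection_floor_used_ = float(floor)
        self.detectable_ = bool(self.percent_mean_ > floor * 100.0)
        return self

    def estimate_(self) -> DonorEstimate:
        """Package the fitted attributes as a :class:`DonorEstimate`."""
        return DonorEstimate(
            percent_mean=self.percent_mean_,
            percent_sd=self.percent_sd_,
            n_replicates=self.n_converged_,
            n_loci_used=self.n_loci_used_,
            detectable=self.detectable_,
            error_rate_mean=self.error_rate_mean_,
            n_nonconverged=self.n_nonconverged_,
            pooled_error_rate=self.pooled_error_rate,
        )


def estimate_donor_fraction(
    loci: Sequence[SelectedLocus] | Sequence[float],
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed=None,
    **kwargs,
) -> DonorEstimate:
    """Estimate the donor percentage from selected loci (thin wrapper).

    ``loci`` may be :class:`SelectedLocus` records or bare fractions;
    remaining keyword arguments go to :class:`DonorFractionEstimator`.
    """
    if len(loci) and isinstance(loci[0], SelectedLocus):
        fractions = [locus.donor_signal_fraction for locus in loci]
    else:
        fractions = list(loci)
    est = DonorFractionEstimator(n_replicates=n_replicates, random_state=seed, **kwargs)
    est.fit(fractions)
    return est.estimate_()


def pool_error_rate(
    fits: Sequence[MixtureFitResult | float], locus_counts: Sequence[int]
) -> float:
    """Locus-count-weighted mean error rate across co-sequenced samples.

    ``fits`` are per-sample mixture fits (or bare ``mu_err`` values) from
    the same sequencing run; ``locus_counts`` are the numbers of selected
    loci each was fit on.
    """
    if len(fits) == 0:
        raise DonorMixError("pool_error_rate requires at least one sample")
    if len(fits) != len(locus_counts):
        raise DonorMixError("one locus count per fit is required")
    counts = np.asarray(locus_counts, dtype=float)
    if np.any(counts <= 0):
        raise DonorMixError("locus counts must be positive")
    mu = np.asarray([f.mu_err if isinstance(f, MixtureFitResult) else float(f) for f in fits])
    return float((mu * counts).sum() / counts.sum())
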