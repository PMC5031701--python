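"""Independent oracles for the mixture-model tests.

Deliberately coded against ``scipy.stats.norm`` (not the package's own
log-density) so that agreement between EM and these functions is a real
cross-check, not a tautology.
"""

import numpy as np
from scipy.stats import norm

WEIGHTS = (0.25, 0.5, 0.25)
SIGMA_FLOOR = 1e-5


def constrained_loglik(x, mu_err, mu_osa, sigma_err, sigma_osa):
    """Log-likelihood of the 1:2:1 mixture with tied OSA:NSA ratios."""
    density = (
        WEIGHTS[0] * norm.pdf(x, mu_err, sigma_err)
        + WEIGHTS[1] * norm.pdf(x, mu_osa, sigma_osa)
        + WEIGHTS[2] * norm.pdf(x, 2 * mu_osa, 2 * sigma_osa)
    )
    with np.errstate(divide="ignore"):
        return float(np.log(density).sum())


def grid_search(x, mu_err_grid, mu_osa_grid, sigma_err_grid, sigma_osa_grid):
    """Brute-force maximizer of the constrained likelihood over a grid."""
    best_ll, best_params = -np.inf, None
    for me in mu_err_grid:
        for mo in mu_osa_grid:
            for se in sigma_err_grid:
                for so in sigma_osa_grid:
                    if se < SIGMA_FLOOR or so < SIGMA_FLOOR:
                        continue
                    ll = constrained_loglik(x, me, mo, se, so)
                    if ll > best_ll:
                        best_ll, best_params = ll, (me, mo, se, so)
    return best_ll, best_params
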