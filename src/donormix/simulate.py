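"""Synthetic two-contributor panel sequencing data with known truth.

The simulator emulates the assay's in-vitro validation: two unrelated
genomes ("recipient" and "donor") mixed at a known fraction, sequenced
over a panel of biallelic SNPs at amplicon-scale depth. Genotypes are
drawn independently per contributor under Hardy-Weinberg equilibrium at
a configurable allele frequency (0.5 by default, matching evenly
biallelic identity-panel SNPs); read depth is negative-binomial
(amplicon coverage overdisperses relative to Poisson); each read comes
from the donor with probability equal to the donor fraction, carries one
of its contributor's two alleles uniformly, and is miscalled to a
uniformly random other base with the per-base error rate.

Under this channel an expected e/3 of errors land on the locus's other
panel allele and 2e/3 on off-panel (ambiguous) bases.

The titration driver reproduces the mixture-series design used to
validate the assay: donor fractions 0, 0.5, 1, 2, 4 and 8 percent, each
in triplicate, scored by the zero-intercept coefficient of
determination between expected and estimated donor percentages.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .counts import LocusBaseCounts, make_counts
from .estimator import estimate_donor_fraction
from .exceptions import ConfigError, UndefinedResultError
from .panel import NUCLEOTIDES, PanelLocus
from .selection import select_loci

logger = logging.getLogger(__name__)

#: Donor fractions of the reference titration series (0–8%).
TITRATION_FRACTIONS = (0.0, 0.005, 0.01, 0.02, 0.04, 0.08)

#: Donor fractions at/above this are outside the method's validity range
#: (the >86% homozygosity call fails in expectation at NSA loci).
VALIDITY_BOUND = 0.14

_BASES = np.array(list("ACGT"))
SHARED_CLASSES = ("both-shared", "one-shared", "none-shared")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated sample.

    Defaults mirror the assay's validation conditions: ~90 autosomal
    biallelic loci at allele frequency 0.5 (so ~45 are expected to be
    recipient-homozygous, near the ~42 informative loci typical of the
    identity panel), mean depth 1500 (the plateau of the
    depth-precision curve), base error rate 0.001 (Q30).
    """

    n_loci: int = 90
    allele_freq: float = 0.5
    donor_fraction: float = 0.0
    depth_mean: int = 1500
    depth_dispersion: float = 5.0
    error_rate: float = 0.001
    seed: int | None = None

    def __post_init__(self):
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if not (0.0 < self.allele_freq < 1.0):
            raise ConfigError("allele_freq must lie in the open interval (0, 1)")
        if not (0.0 <= self.donor_fraction < 1.0):
            raise ConfigError("donor_fraction must lie in [0, 1)")
        if self.donor_fraction >= VALIDITY_BOUND:
            logger.warning(
                "donor_fraction %.3f is at/above the %.0f%% validity bound of the "
                "homozygosity-based method", self.donor_fraction, VALIDITY_BOUND * 100,
            )
        if not (0.0 <= self.error_rate < 0.25):
            raise ConfigError("error_rate must lie in [0, 0.25)")
        if self.depth_mean < 1:
            raise ConfigError("depth_mean must be >= 1")
        if self.depth_dispersion <= 0:
            raise ConfigError("depth_dispersion must be positive")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth genotypes and sharing class for one simulated locus."""

    locus_id: str
    recipient_genotype: tuple
    donor_genotype: tuple
    shared_class: str = field(init=False)

    def __post_init__(self):
        rec = set(self.recipient_genotype)
        n_shared = sum(a in rec for a in self.donor_genotype)
        object.__setattr__(self, "shared_class", SHARED_CLASSES[2 - n_shared] if n_shared < 2 else SHARED_CLASSES[0])


def _rng(config: SimulationConfig, seed=None) -> np.random.Generator:
    if seed is None:
        seed = config.seed
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_panel(config: SimulationConfig, rng=None) -> list[PanelLocus]:
    """Synthesize an autosomal biallelic panel of ``n_loci`` SNPs.

    Loci cycle through chromosomes 1-22 at spaced positions; each locus
    gets a random pair of distinct alleles.
    """
    rng = _rng(config, rng)
    loci = []
    chroms = itertools.cycle(str(c) for c in range(1, 23))
    for i, chrom in zip(range(config.n_loci), chroms):
        a, b = rng.choice(4, size=2, replace=False)
        loci.append(
            PanelLocus(
                locus_id=f"sim{i + 1:04d}",
                chrom=chrom,
                pos=1_000 * (i // 22 + 1) + i,
                allele_a=str(_BASES[a]),
                allele_b=str(_BASES[b]),
                is_autosomal=True,
            )
        )
    return loci


def simulate_genotypes(
    config: SimulationConfig, panel: Sequence[PanelLocus] | None = None, rng=None
) -> tuple[list[PanelLocus], list[TruthRecord]]:
    """Draw recipient and donor genotypes under Hardy-Weinberg equilibrium.

    Contributors are independent (unrelated pair); ``allele_freq`` is the
    population frequency of ``allele_b``. Returns the panel together
    with one :class:`TruthRecord` per locus; reproducible under seed.
    """
    rng = _rng(config, rng)
    if panel is None:
        panel = simulate_panel(config, rng)
    truth = []
    for locus in panel:
        alleles = (locus.allele_a, locus.allele_b)
        draws = rng.random(4) < config.allele_freq  # True -> allele_b
        rec = tuple(sorted(alleles[int(d)] for d in draws[:2]))
        don = tuple(sorted(alleles[int(d)] for d in draws[2:]))
        truth.append(TruthRecord(locus.locus_id, rec, don))
    return list(panel), truth


def simulate_counts(
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    panel: Sequence[PanelLocus],
    rng=None,
) -> list[LocusBaseCounts]:
    """Sample per-locus base counts for a two-contributor mixture.

    Per locus: depth ~ NegativeBinomial(mean=depth_mean,
    dispersion=depth_dispersion); each read originates from the donor
    with probability ``donor_fraction``, carries an allele drawn
    uniformly from that contributor's genotype, and is miscalled to one
    of the three other bases (uniformly) with probability
    ``error_rate``. Tallied counts always sum to the drawn depth.
    """
    if not truth:
        raise ConfigError("truth records are empty")
    rng = _rng(config, rng)
    by_id = {locus.locus_id: locus for locus in panel}
    e, x = config.error_rate, config.donor_fraction
    k = config.depth_dispersion
    p_nb = k / (k + config.depth_mean)
    out = []
    for rec in truth:
        locus = by_id[rec.locus_id]
        # per-base emission probabilities of the mixture-of-contributors channel
        p = np.zeros(4)
        for genotype, w in ((rec.recipient_genotype, 1.0 - x), (rec.donor_genotype, x)):
            for allele in genotype:
                idx = int(np.where(_BASES == allele)[0][0])
                p += (w * 0.5) * (e / 3.0) * (np.arange(4) != idx)
                p[idx] += (w * 0.5) * (1.0 - e)
        depth = int(rng.negative_binomial(k, p_nb))
        tally = rng.multinomial(depth, p) if depth > 0 else np.zeros(4, dtype=int)
        counts = make_counts(locus, dict(zip(_BASES, tally)))
        out.append(counts)
    return out


def simulate_sample(config: SimulationConfig, rng=None):
    """Full synthetic sample: panel, truth, counts (one seeded draw)."""
    rng = _rng(config, rng)
    panel, truth = simulate_genotypes(config, rng=rng)
    counts = simulate_counts(truth, config, panel, rng=rng)
    return panel, truth, counts


def zero_intercept_r2(expected: Sequence[float], estimated: Sequence[float]) -> float:
    """Coefficient of determination of the least-squares line through the
    origin: fit ``y = b x`` and return ``1 - sum((y - b x)^2) / sum(y^2)``.

    The slope absorbs any proportional scale difference; the statistic
    measures linearity through zero, not slope accuracy.
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(estimated, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise UndefinedResultError("need matched expected/estimated series of length >= 2")
    sxx = float(x @ x)
    if sxx == 0.0:
        raise UndefinedResultError("all expected values are zero; slope undefined")
    syy = float(y @ y)
    if syy == 0.0:
        raise UndefinedResultError("all estimated values are zero; R^2 undefined")
    b = float(x @ y) / sxx
    return 1.0 - float(((y - b * x) ** 2).sum()) / syy


def run_titration(
    fractions: Sequence[float] = TITRATION_FRACTIONS,
    replicates: int = 3,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    n_em_replicates: int = 200,
    **estimator_kwargs,
) -> tuple[pd.DataFrame, float | None]:
    """Simulate and score a donor-fraction titration series.

    For each donor fraction x replicate, a full pipeline run (simulate
    genotypes and counts, select recipient-homozygous loci, fit the
    replicate-aggregated mixture estimator) produces an estimated donor
    percentage. Returns the per-sample table and the zero-intercept R²
    of estimated vs expected percentages (None when undefined, e.g. a
    single all-zero fraction).

    Deterministic for a given seed: per-sample seeds are spawned from a
    master seed sequence.
    """
    if any(f < 0 or f >= VALIDITY_BOUND for f in fractions):
        raise ConfigError(
            f"titration fractions must lie in [0, {VALIDITY_BOUND}) — the method's validity range"
        )
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    base = config or SimulationConfig()
    master = np.random.SeedSequence(seed if seed is not None else base.seed)
    children = master.spawn(len(fractions) * replicates * 2)
    rows = []
    i = 0
    for frac in fractions:
        cfg = replace(base, donor_fraction=frac)
        for rep in range(1, replicates + 1):
            sim_rng = np.random.default_rng(children[i])
            est_seed = int(children[i + 1].generate_state(1)[0] % (2**31))
            i += 2
            panel, truth, counts = simulate_sample(cfg, rng=sim_rng)
            selected, _ = select_loci(counts, panel)
            est = estimate_donor_fraction(
                selected, n_replicates=n_em_replicates, seed=est_seed, **estimator_kwargs
            )
            rows.append(
                {
                    "expected_percent": frac * 100.0,
                    "replicate": rep,
                    "estimated_percent": est.percent_mean,
                    "estimated_sd": est.percent_sd,
                    "n_loci": est.n_loci_used,
                    "detectable": est.detectable,
                }
            )
    table = pd.DataFrame(rows)
    try:
        r2 = zero_intercept_r2(table["expected_percent"], table["estimated_percent"])
    except UndefinedResultError:
        logger.warning("zero-intercept R^2 not applicable for this titration design")
        r2 = None
    return table, r2


def write_truth_table(truth: Iterable[TruthRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "locus_id": t.locus_id,
                "recipient_genotype": "".join(t.recipient_genotype),
                "donor_genotype": "".join(t.donor_genotype),
                "shared_class": t.shared_class,
            }
            for t in truth
        ]
    )
    df.to_csv(path, sep="\t", index=False)
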