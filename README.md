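# donormix

Genotyping-free estimation of the donor-derived fraction of cell-free DNA
(cfDNA) from targeted SNP-panel sequencing.

After a solid-organ or cell transplant, DNA released by dying graft cells
circulates in the recipient's plasma; a rising donor-derived cfDNA
fraction is a non-invasive marker of allograft injury and rejection.
`donormix` quantifies that fraction from deep amplicon sequencing of any
biallelic SNP panel (such as a forensic identity panel), **without
genotyping either donor or recipient**, so it works when no donor sample
is available.

## Method

At a biallelic SNP where the recipient (the major contributor, fraction
`1 - x`) is homozygous, every read carrying the other panel allele comes
from donor DNA or from sequencing error. The pipeline:

1. **Count** — tally per-base read counts at each panel locus, keeping
   only calls with base quality ≥ Q30 (theoretical error rate
   10⁻³⁰ᐟ¹⁰ = 0.001).
2. **Select** — keep autosomal loci with adequate depth, ≤ 5% ambiguous
   calls, and a homozygous recipient: one panel allele in **> 86%** of all
   quality-passing reads. The hard 86% call bounds validity: the method
   applies only for donor fractions below ~14%.
3. **Deconvolve** — the per-locus minor-allele fractions
   `f_i = n_minor / (n_minor + n_major)` are a mixture of three signal
   classes determined by the (unknown) donor genotype. For unrelated
   contributors at evenly biallelic loci the classes occur 1 : 2 : 1:

   | donor vs recipient | weight | minor-allele signal |
   |---|---|---|
   | both alleles shared   | 1/4 | error rate *e* |
   | one shared allele (OSA) | 1/2 | *x*/2 |
   | no shared allele (NSA)  | 1/4 | *x* |

   A three-component Gaussian mixture is fit by EM with linear
   constraints: mixing weights **fixed** at (¼, ½, ¼), and tied ratios
   μ_NSA = 2 μ_OSA and σ_NSA = 2 σ_OSA. The error mean starts at 0.1%
   (the Q30 rate) and is re-estimated. The donor-fraction estimate from
   one fit is `max(0, μ_NSA − μ_err)`.
4. **Aggregate** — because the constrained EM is sensitive to its start,
   the fit is repeated from 10,000 randomized initializations; the mean
   and SD of the per-replicate estimates are reported (percent scale),
   together with a detectability call against the platform noise floor
   (the pooled error rate of co-sequenced samples, or 0.1% by default).

The model core follows the scikit-learn estimator API
(`ConstrainedGaussianMixture`, `DonorFractionEstimator`), and a seeded
simulator generates two-contributor panel data with known truth,
including the 0–8% titration series used for validation.

## Worked example

Simulate a sample with a true donor fraction of 2% and estimate it:

```sh
$ donormix simulate --out-dir sim --donor-fraction 0.02 --seed 20
wrote panel.bed, counts.tsv, truth.tsv to sim
$ donormix estimate --panel sim/panel.bed --counts sim/counts.tsv \
      --out-dir est --seed 5 --n-replicates 1000
donor cfDNA: 2.018% +/- 0.000% (54 loci, detectable=True)
```

Of the 90 simulated loci, 54 were recipient-homozygous and informative;
their minor-allele fractions yield a donor estimate of 2.018% against a
2% truth. The replicate SD is ~0 here because every EM restart reaches
the same optimum on this clean, deep (1500×) sample; noisier inputs show
restart-to-restart spread. `est/estimate.json` carries the full record
(estimate, SD, locus drop counts per selection stage, fitted error rate,
detectability), `est/selection_report.tsv` the per-locus decisions, and
`est/run_log.json` the seed and thresholds needed to replay the run.

The same workflow runs from a samtools text pileup via
`donormix count --panel ... --pileup ...`, and `donormix pool` combines
the fitted error rates of samples sequenced on the same chip into the
pooled noise floor. In Python:

```python
from donormix import SimulationConfig, simulate_sample, select_loci, estimate_donor_fraction

panel, truth, counts = simulate_sample(SimulationConfig(donor_fraction=0.02, seed=20))
selected, report = select_loci(counts, panel)
est = estimate_donor_fraction(selected, n_replicates=1000, seed=5)
print(est.percent_mean, est.detectable)   # 2.0175... True
```

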