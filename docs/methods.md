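# Methods

## Model

A two-contributor DNA mixture is observed through deep sequencing of a
panel of biallelic SNPs. Let `x` be the minor ("donor") contributor's
fraction and `e` the per-base error rate of quality-passing calls. At a
locus where the major ("recipient") contributor is homozygous, the
minor-allele fraction over the two panel alleles falls into one of three
classes, depending on how many donor alleles coincide with the
recipient's: both (signal ~ error), one (signal ~ x/2), none
(signal ~ x). For unrelated contributors and allele frequency ~0.5 the
classes occur with probability ¼ : ½ : ¼ among recipient-homozygous
loci, so the per-locus fractions are modelled as a three-component
Gaussian mixture with

- mixing weights fixed at (0.25, 0.5, 0.25) — a constraint, never
  re-estimated;
- tied component ratios μ_NSA = 2 μ_OSA and σ_NSA = 2 σ_OSA;
- free error component (μ_err, σ_err), initialized at μ_err = 0.001
  (the theoretical Q30 error rate) and re-estimated by EM.

The EM M-step under the ties has a closed form (the
responsibility-weighted least-squares solution):

    μ_err = Σ r₁ᵢxᵢ / Σ r₁ᵢ
    μ_OSA = (Σ r₂ᵢxᵢ + ½ Σ r₃ᵢxᵢ) / (Σ r₂ᵢ + Σ r₃ᵢ)
    σ²_OSA = (Σ r₂ᵢ(xᵢ−μ_OSA)² + ¼ Σ r₃ᵢ(xᵢ−2μ_OSA)²) / (Σ r₂ᵢ + Σ r₃ᵢ)

so the log-likelihood is non-decreasing at every iteration, and the
constraint ratios hold exactly after every M-step (asserted in tests).
The per-fit donor estimate is `max(0, μ_NSA − μ_err)`.

The 1:2 mean tie is an approximation: physically the OSA and NSA
signals are ~x/2 + O(e) and ~x + O(e), whose ratio is exactly 2 only
when e ≪ x. It is enforced as stated because it makes the
four-parameter fit identifiable on ~40 observations, and the
regime the assay targets (x up to a few percent, e ~ 0.1%) keeps the
approximation error well below the sampling noise.

## Replicate aggregation

Constrained EM on small samples has multiple basins of attraction, so a
point estimate from one start is not reproducible. The estimator
therefore repeats the fit from randomized starting points and reports
the mean and SD of the converged replicates' estimates (×100, percent
scale). Initial means are drawn log-uniformly around deterministic
anchors: μ_err ~ 0.001·LogUniform(0.5, 2) and
μ_OSA ~ median(f)·LogUniform(0.25, 4) — the OSA component carries half
the mixture weight, so the sample median sits in its cluster — with
sigmas starting at half the means. All replicate draws descend from a
single master seed, so runs are replayable bit-for-bit. Bootstrap
resampling of loci per replicate is available (`bootstrap=True`) as an
alternative source of replicate variation, but random restarts are the
default. Non-converged replicates are excluded and counted.

Detectability: a sample is "detectable" when the mean estimate exceeds
the platform noise floor. The floor is the pooled (locus-count-weighted)
error rate across samples of the same sequencing run when supplied;
otherwise a configurable `detection_floor` defaulting to the theoretical
Q30 rate 0.001. The per-sample fitted μ_err is reported but not used as
the floor: on a true-zero sample, where most locus fractions are exactly
0, the EM can park the error component at ~0 and the fitted μ_err stops
being a meaningful noise estimate. The donor estimate itself always
subtracts the per-replicate fitted μ_err; the pooled rate is reported
alongside and can be substituted via configuration.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| min_base_quality | 30 | Phred | Q30 ⇒ theoretical error 0.001 |
| homozygosity_threshold | 0.86 | fraction of all quality-passing reads | recipient-homozygous call (> strict); implies the <14% validity bound |
| max_ambiguous_fraction | 0.05 | fraction of all quality-passing reads | loci with more off-panel/N calls are excluded (> strict) |
| min_depth | 100 | reads | floors the per-locus binomial noise; estimates degrade sharply at low depth |
| n_replicates | 10,000 | — | EM restarts aggregated into mean ± SD |
| tol / max_iter | 10⁻⁸ / 500 | log-likelihood / iterations | standard EM stopping rule |
| variance_floor | 10⁻⁵ | fraction (σ) | prevents degenerate spikes on near-constant data; the floored σ is still the constrained M-step maximizer, preserving EM ascent |
| detection_floor | 0.001 | fraction | Q30 noise floor used when no pooled rate is given |

Threshold conventions, decided where the rules could be read two ways:
the homozygosity and ambiguity denominators are the *total*
quality-passing depth (ambiguous calls included) — the conservative
reading; the donor-signal fraction is computed over the two panel
alleles only, since the mixture's three classes are defined on them.
Exactly 86% is not homozygous and exactly 5% ambiguous is retained
(both rules strict `>`). A quality-passing call of N or of a base that
is neither panel allele counts as ambiguous. Y-chromosome (and all
non-autosomal) loci are excluded from the model.

## Simulator

`donormix.simulate` emulates the titration experiment used to validate
the assay in vitro: two unrelated genomes mixed at known fractions and
sequenced over the panel. Genotypes are drawn independently per
contributor under Hardy-Weinberg equilibrium (allele frequency 0.5 by
default, matching evenly biallelic identity-panel SNPs); depth is
negative-binomial with mean 1500 (the plateau of the depth-precision
curve) and dispersion 5, since amplicon coverage overdisperses relative
to Poisson; each read originates from the donor with probability x,
carries one of its contributor's alleles uniformly, and is miscalled to
a uniformly random other base with probability e = 0.001. Under this
channel e/3 of errors land on the locus's other panel allele and 2e/3
off-panel. The default 90 autosomal loci give ~45 expected
recipient-homozygous loci, near the ~40 informative loci typical of a
124-SNP identity panel — a convention, not a measured panel property.

The titration driver runs donor fractions (0, 0.5, 1, 2, 4, 8)% in
triplicate through the full pipeline and scores the zero-intercept
coefficient of determination, `R² = 1 − Σ(y − bx)²/Σy²` with
`b = Σxy/Σx²`; `run_titration` defaults to 200 EM restarts per sample,
a desk-scale setting that leaves the R² statistic unchanged relative to
the full 10,000.

What the simulator does **not** emulate: PCR/amplicon bias and
duplicates, strand artifacts, context-dependent or systematically
skewed error spectra, related donor–recipient pairs, contamination by
a third contributor, and locus-specific allele frequencies. Passing
tests therefore demonstrate correctness of the selection rules and the
constrained estimator under idealized sampling noise, not robustness to
platform-specific artifacts on real plasma libraries.

## Numerical and design choices

- Gaussian components only; no gamma alternative.
- Negative per-fit estimates are clamped to 0 before aggregation;
  "not detectable" is reported instead of negative percentages.
- Fits need ≥ 6 locus fractions; fewer is refused as insufficient data.
- Degenerate near-constant input collapses the sigmas to the variance
  floor; the resulting estimate is at the error-rate scale (~0.1%), as
  cross-checked against a brute-force grid search of the same
  constrained likelihood.
- Panel positions are 1-based internally (pileup convention); BED input
  is converted on read. `chr` prefixes are stripped. Panel allele order
  carries no reference/alternate meaning.
- Problem sizes in the test suite (e.g. 200 restarts, 60-point grid
  oracles, 12–20 simulated datasets per property) are chosen as the
  smallest sizes at which the checked effects are statistically
  unambiguous.

## Limitations

- Valid only for donor fractions below ~14% (the homozygosity call
  fails at NSA loci beyond it); practically targeted at the 0–8% range.
- Unrelated contributors are assumed; shared ancestry shrinks the
  informative locus set and biases the 1:2:1 weights.
- Exactly two contributors; no multi-donor mixtures.
- Reports a relative fraction, not absolute donor copies per mL.
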