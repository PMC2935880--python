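# Methods

## Disease model and test statistic

The engine models a biallelic SNP under a multiplicative (log-additive)
risk model: carrying g copies of the risk allele multiplies disease risk
by GRR^g, with the effect size assumed identical in every population.
Within each population, genotypes are assumed to follow Hardy–Weinberg
equilibrium; a useful consequence of the multiplicative model is that
case genotypes remain in HWE at the shifted allele frequency
p_case = p·GRR/(p·GRR + 1 − p), so case and control allele counts are
exactly binomial. Two control models are exposed:

* **rare-disease approximation** (default): controls are drawn from the
  general population, p_control = p;
* **explicit prevalence K**: the per-genotype penetrances f·GRR^g are
  anchored so the population prevalence is K, cases follow the
  penetrance-weighted genotype mixture and controls the complement. The
  mixture identity K·p_case + (1−K)·p_control = p holds exactly and is
  tested.

The association test is the 1-df allele-count chi-square. Its
non-centrality parameter for one case-control arm is

    NCP = (p_case − p_control)² / [ p̄(1−p̄)·(1/(2N_case) + 1/(2N_control)) ],

where p̄ is the sample-size-weighted pooled allele frequency under the
alternative. At fixed frequencies the NCP is linear in sample size and
additive over independent arms, which is what makes two-phase and
multiethnic designs composable: the total evidence of a scenario is the
sum of its arms' NCPs. Power is P[χ²(df=1, NCP) > q] with q the central
critical value at the significance level α (5×10⁻⁸ for genome-wide
discovery, 0.05 for replication of a pre-specified hypothesis). The
upper tail is always evaluated through survival functions so that powers
of order α survive floating-point cancellation, and results are clipped
to the mathematically valid interval [α, 1] (at NCP of order 1e-100 the
noncentral survival function can round a few ulp below α).

Because which allele drives risk is unknown in a genome scan, per-SNP
power defaults to the average of the two powers obtained with either
allele treated as risk-increasing; at GRR = 1 both orientations coincide
and power equals α exactly.

### Validation

A genotype-level Monte-Carlo oracle draws case genotypes from the
GRR-reweighted HWE distribution and control genotypes from HWE, scores
each replicate with the allelic 2×2 chi-square, and estimates power as
the exceedance fraction. The analytic power agrees with this oracle
within Monte-Carlo error across a frequency × effect-size × sample-size
grid at α ∈ {0.05, 0.001}; at genome-wide α the tail is not reachable by
simulation, and the NCP itself is validated through the mean identity
E[χ²] = 1 + NCP. One caveat is documented by the test suite itself: at
the extreme corner p = 0.01, GRR = 1.5, 2,500/2,500, α = 0.001 the
asymptotic noncentral-chi-square power overestimates the exact binomial
power by ≈0.005 (the expected minor-allele count is only ~50 and the
binomial left tail is skewed), which is just over three Monte-Carlo
standard errors at 50,000 replicates. This is an intrinsic limitation of
asymptotic power at small expected counts, not of the implementation; at
the other 47 grid points agreement is comfortable.

## Scenarios

A scenario is two phases, each a list of (panel, N_case, N_control)
arms. The three presets fix phase 1 to CEU and split totals as
2,500/2,500 + 2,500/2,500 (10k), 5,000/5,000 + 5,000/5,000 (20k) and
10,000/10,000 + 30,000/30,000 (80k). Multiethnic phase-2 designs divide
cases and controls as evenly as integers allow across panels, assigning
remainders to the earliest panels in list order — the split proportions
are a design choice (nothing forces equality), made symmetric and
deterministic so totals are conserved exactly. Zero-size phases are
legal and contribute nothing.

## Genome-wide aggregation

Per-SNP powers are computed vectorized over the whole frequency table
and summarized as unweighted means within minor-allele-frequency strata
of a reference panel. The default partition of MAF is: monomorphic {0};
(0, 0.01); [0.01, 0.05] — the "low-frequency" band; (0.05, 0.10];
(0.10, 0.50]. Which endpoints are closed is a convention; the one above
keeps 1% and 5% inside the low-frequency band. The genome-wide mean is
the SNP-count-weighted recombination of the stratum means (tested as an
identity). SNPs with a missing frequency in some panel contribute zero
NCP from that panel's arms.

Two scenarios are compared three ways:

* **threshold categories** — counts of SNPs reaching a power threshold
  (default 80%) in both, only one, or neither scenario;
* **frequency-difference classes** — for each SNP the allele that is
  minor in the reference panel (ties at exactly 0.5 anchored to
  allele_a) is followed into the other panel and its two frequencies
  compared. Anchoring to one panel's minor allele deliberately ignores
  allele flips: the question is whether the *same* allele is more common
  elsewhere. Exact equality defines the "equal" class by default
  (finite-chromosome estimates are discrete, so exact ties are common); a
  tolerance knob is exposed. SNPs monomorphic in both panels are
  excluded;
* **gain by difference** — SNPs binned by the anchored frequency
  difference (half-open [lo, hi) bins, width 0.05) with the mean power
  change per bin. With a drifted second-phase panel, bins with
  elevation roughly +15% to +40% show a positive mean gain, the
  mechanism by which multiethnic designs rescue low-frequency alleles.
  The gain curve is *not* monotone in the elevation: in the sparse
  extreme bins (elevation ≳ +0.70) the anchored allele approaches
  fixation in the drifted panel, where it stops contributing evidence
  and the mean change turns negative. The acceptance test therefore
  asserts positivity over the +15–40% regime, where the effect is
  systematic.

## Replication sizing

For a reported association (risk allele, odds ratio used as the GRR),
the calculator finds the smallest even total N (cases = controls = N/2)
whose analytic power at nominal α = 0.05 reaches the target (default
80%) in each panel, by bisection on the monotone power-in-N function
followed by integer refinement; every reported N satisfies
power(N) ≥ target > power(N − 2). Panels where the risk allele is fixed
are NA; when even the cap (default 150,000 samples) is insufficient the
result carries the power at the cap. The report compares each
association's reference-panel N against the smallest N among the other
panels, counting efficiency gains and losses, and flags associations
needing at least 2,500 samples in the reference panel. The minimal-even-N
convention (rather than rounding per arm) is a documented choice.

## Synthetic data

The generator emulates the statistical structure of multi-population
frequency resources:

* **drift**: each panel's frequency is an independent Balding–Nichols
  draw Beta(q(1−F)/F, (1−q)(1−F)/F) around the ancestral frequency q
  (mean q, variance F·q(1−q)); F = 0 reproduces q exactly. F ≈ 0.005
  mimics closely related panels, F ≈ 0.10–0.15 continental separation —
  configurable defaults, chosen to land the simulated frequency
  elevations in the 15–40% regime where the power mechanism operates;
* **ancestral spectrum**: density ∝ 1/x on [0.001, 0.999] by default
  (neutral-like excess of rare alleles; sampled by exact inverse CDF),
  with uniform and Beta alternatives;
* **ascertainment**: array-like input keeps SNPs with reference-panel
  MAF ≥ a cutoff (1% mimics genotyping arrays; 0 mimics sequencing);
* **finite founders**: frequencies re-estimated as binomial counts over
  a fixed number of chromosomes (100 chromosomes = 50 founders matches
  the convention of equalizing panel precision), making estimates
  discrete and unbiased.

What the generator does **not** emulate: linkage disequilibrium between
tag and causal variants (the analysis is frequency-only by
construction), admixture (panels drift independently in a star
topology; admixed panels could be composed as mixtures but are off by
default), effect-size heterogeneity across populations, and population
stratification within a cohort. Tests passing on synthetic data
demonstrate the machinery and the drift mechanism, not the empirical
frequency spectra of any real panel; the pipeline reproduces
real-data results when given real frequency tables.

## Problem sizes and determinism

The test suite and the acceptance script run genome scans at 50,000
simulated SNPs and Monte-Carlo validation at 50,000 replicates — sizes at
which stratum means are stable to a few tenths of a percent and the
whole pipeline completes in seconds. Every stochastic component takes an
explicit seed; the command-line pipeline writes frequencies at six
decimals and JSON with sorted keys, so a fixed seed reproduces every
output byte for byte.
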