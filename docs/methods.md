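# Methods

## The problem and the model

`mhcrec` estimates a per-generation recombination rate for a multi-marker
region from a single cross-sectional sample of a population that was founded
by a small, dated introduction and then expanded. The motivating system is
the MHC of the Mauritian long-tailed macaque: ~12 founders introduced ~400
years ago, seven founding MHC haplotypes typed at 17 microsatellites, 750
sampled animals (1500 haplotypes).

The estimator rests on three ingredients:

1. **Mosaic parsimony.** Every sampled haplotype is explained as a mosaic of
   the founding haplotypes with the minimum number of crossover switches
   *h*. Because microsatellite alleles are widely shared between founders,
   *h* is a lower bound on the true crossover history, and switch positions
   are located only up to an interval of inter-marker gaps.
2. **Poisson accumulation.** If crossovers are rare, occur at a constant
   per-meiosis probability *c* since founding, do not interact, and are
   selectively neutral, the number of detectable crossovers per transmitted
   lineage after *G* generations is Poisson with intensity λ = c·G (up to
   detectability, below). The MLE of λ is the spectrum mean
   λ̂ = Σ k·n_k / n; its Wald interval is λ̂ ∓ u_{α/2}·√(λ̂/n). Fit quality
   is a Pearson χ² against the Poisson expectation, with cells pooled from
   the upper tail downward until every expected count reaches 5, and
   df = (pooled bins) − 2 (one df spent on the estimated intensity).
3. **Detectability.** A crossover between two haplotypes carrying the same
   founder locally is invisible, so λ̂/G estimates the *detectable* rate;
   dividing by the population's heterozygote frequency (0.90 here)
   approximates the total rate.

The demography module supplies the comparison with coalescent-scaled
estimates: a logistic (Verhulst) census
N_t = N0·K / (N0 + (K − N0)·e^(−r0·t)), the harmonic-mean effective size
over generations t = 1..T (the founder generation t = 0 is excluded; this
convention is required to reproduce the published extremes 63–3252), and the
algebra c = ρ/(4·Ne). The harmonic mean is dominated by the early, small
generations, which is why Ne — and hence any rate derived from ρ — is so
sensitive to N0 and r0 in such populations.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| elapsed time | 400 | years | founding date of the Mauritian population |
| generation time | 4 and 8 | years | plausible macaque range; G = 100 or 50 |
| heterozygote frequency | 0.90 | — | observed homozygote frequency ≈ 10% |
| K | 12,000 | animals/generation | one quarter of the ~48,000 census |
| N0 grid | 12–90 | animals | founder estimate to upper plausibility |
| r0 grid | 0.1–0.4 | per generation | published exploration range |
| min expected count | 5 | haplotypes | χ² validity rule |
| α | 0.05 | — | confidence level |

## Numerical and algorithmic choices

- **Parsimony DP.** `best[m, f] = penalty(m, f) + min(best[m−1, f],
  1 + min_g best[m−1, g])` with an infinite penalty for incompatibility;
  marker order is fixed telomere→centromere, indices 0-based, all ranges
  half-open. Segments and breakpoint intervals come from the equivalent
  greedy maximal-run segmentation; the suite cross-checks the optimum
  against exhaustive mosaic enumeration on 200 random instances.
- **Orphan alleles** (in no founder) default to
  "count-as-mutation-and-ignore": the marker becomes a wildcard and is
  logged, mirroring the treatment of rare alleles as post-founding
  mutations. `wildcard` and `error` policies are selectable. Missing
  alleles are always wildcards; haplotypes with > 50% missing markers are
  rejected (configurable).
- **Ambiguous flanks.** Where several founders can carry a recombinant's
  end segment, the flanking-founder distribution splits the haplotype's
  mass equally among candidates by default; a `drop` policy discards
  ambiguous haplotypes. Nothing in the source analysis fixes this rule, so
  both are exposed.
- **Bin pooling direction.** Pooling proceeds from the upper tail downward
  (the sparse high-k classes collapse into an open-ended ≥k bin, which
  reproduces the published {0},{1},{2},{≥3} grouping); the df rule refuses
  to report a p-value when pooling leaves fewer than three bins.
- **Fixed-λ GOF.** The test can be run with a user-supplied λ; df stays
  bins − 2 in both modes so the two are comparable (a caveat, since no
  parameter was estimated in the fixed mode).
- **Rounding** happens only in report display blocks; all internal values
  are full precision. u_{α/2} is computed from the normal quantile, never
  hard-coded.

## The synthetic-data generator

`simulate` regenerates the study conditions: a founder generation of N0
diploids drawing haplotypes from the founder pool, census sizes
round(N_t) of the logistic trajectory, non-overlapping generations, two
distinct uniformly drawn parents per offspring, one Bernoulli(c) crossover
per meiosis at a uniform inter-marker gap (no hotspots; c ≈ 0.004–0.008
over ~3 Mb makes double crossovers negligible — a Poisson-crossover mode
exists for stress tests), and stepwise mutation (± one repeat unit,
default μ = 1e-4 per marker per meiosis, the order of magnitude implied by
the rarity of non-founder alleles in the sample).

Ground truth is tracked as *junctions*: each haplotype carries, per
inter-marker gap, the number of crossover events in its ancestry that
created a junction there; a new crossover at a gap replaces whatever
history sat at that exact gap. The per-haplotype junction total has
expectation c·T and, with mutation off, is always ≥ the parsimony count —
both properties are asserted in the suite.

Defaults the generator does **not** take from the source study:

- founder haplotype frequencies at introduction are unknown; the default is
  uniform over the seven founders (configurable), which makes simulated
  homozygosity ≈ 1/7 plus drift rather than the observed ≈ 10%.

What the simulator deliberately omits — and hence what passing recovery
tests do *not* establish about real data: mating structure (dominant-male
preference, female philopatry), overlapping generations, selection on MHC
haplotypes, genotyping error, and recombination hotspots. With μ > 0 a
stepwise mutation can land on another founder's allele (homoplasy) and
masquerade as one or two extra switches; at μ = 1e-4 this inflates the
spectrum by well under a percent, but it is the reason the
truth-bounds-parsimony invariant is only exact without mutation.

## Validation experiments and problem sizes

`recovery_experiment` runs simulate → classify → fit per replicate and
reports λ̂/T against the true c, CI coverage, and the fraction of true
events invisible to parsimony. At the study scale (12 → 12,000, T = 100,
750 animals, uniform founders, c = 0.004) the median λ̂/T sits ~5–10%
below c — the expected detectability loss — and within the 25% recovery
band over 20 replicates. Interval coverage is checked on 2000 synthetic
Poisson spectra at n = 1500, λ = 0.38 (the Wald interval achieves ≈ 95%
nominal coverage there). Smoke tests use scaled-down demographies
(K ≈ 300–600, T ≤ 40), where drift makes homozygosity — and therefore the
detectability deficit — much larger; those tests assert the direction and
bounds of the effect rather than tight recovery.

## Known limitations

- Parsimony undercounts: reported rates are detectable rates; the
  heterozygosity division is a first-order correction only.
- The method needs a firmly dated founding event and an external generation
  time; uncertainty in either propagates linearly into c.
- Identity-by-descent among identical recombinant haplotypes is ignored
  (each copy counts as an independent lineage), which overstates the
  effective sample size in strongly drifted populations.
- Statistical phasing is out of scope: inputs are phased haplotypes. The
  bundled `naive_phase` handles only founder-anchored genotypes and exists
  for simulator round-trips.
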