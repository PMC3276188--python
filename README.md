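# mhcrec

Per-generation recombination-rate estimation from the recombinant-haplotype
spectrum of an expanding population with a dated founding event.

## The problem

In a population founded by a handful of animals at a known date — the
archetype is the Mauritian long-tailed macaque, founded ~400 years ago by
~12 individuals — every present-day haplotype of a multi-marker region is a
mosaic of the small set of founding haplotypes. Counting the minimum number
of crossover switches *h* needed to explain each sampled haplotype gives a
recombination spectrum n₀, n₁, n₂, … . If crossovers are rare, constant in
time, independent and neutral, the per-lineage count after *G* generations
is Poisson:

- intensity (MLE): λ̂ = Σ k·n_k / n
- confidence interval: λ̂ ∓ u_{α/2}·√(λ̂/n)
- fit quality: Pearson χ² over cells pooled until every expected count ≥ 5,
  df = bins − 2
- per-generation rate: c = λ̂ / G, corrected for invisible events in
  founder-homozygous carriers by dividing by the heterozygote frequency

A demography module (logistic Verhulst growth, harmonic-mean Nₑ over the
post-founding period, c = ρ/4Nₑ) supports comparison with coalescent-scaled
estimates, and a forward-time simulator regenerates the study conditions to
validate the estimator by parameter recovery.

The package ships the published inputs as fixtures: the 17-microsatellite ×
7-founder haplotype table of the Mauritian macaque MHC and the observed
spectrum (1030, 382, 74, 14) of 1500 classified haplotypes.

## Worked example

```sh
mhcrec estimate            # packaged Mauritian spectrum, defaults
```

prints (abridged):

```
lambda   0.3813            # mean recombinations per haplotype since founding
ci       (0.3501, 0.4126)  # 95% Wald interval
gof      chi2 = 1.436, df = 2, p = 0.488   # bins {0},{1},{2},{>=3}
rates    gen time 4 y: detectable 0.0038, corrected 0.0042 per generation
         gen time 8 y: detectable 0.0076, corrected 0.0085 per generation
```

Read: the 1500 haplotypes carry on average 0.38 detectable crossovers
accumulated over 400 years; the Poisson law fits (p ≈ 0.49); depending on
whether a macaque generation is 4 or 8 years, that is 0.4–0.8% recombination
per generation across the region, or ~0.42–0.85% after correcting for
events hidden in founder-homozygous animals.

The same numbers are available programmatically:

```python
import mhcrec as M

spectrum = M.load_mauritius_spectrum()
fit = M.PoissonFit.from_spectrum(spectrum)          # 0.3813 (0.3501, 0.4126)
gof = M.gof_test(spectrum)                          # chi2 1.436, df 2, p 0.488
rate = M.per_generation_rate(fit.lambda_hat, 400, 4)  # 0.0038

ne = M.harmonic_mean_ne(M.VerhulstParams(90, 12000, 0.4), 100).ne  # 3251.45
```

Other subcommands: `mhcrec classify` (phased haplotypes → spectrum via the
founder-mosaic parsimony classifier), `mhcrec demography` (trajectory and
harmonic-mean Nₑ, optional grid sweep), `mhcrec simulate` (forward
simulation with ground-truth mosaics), `mhcrec run` (full pipeline to a
JSON report).

See `docs/methods.md` for the model, its assumptions, and what the
validation experiments do and do not establish.

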