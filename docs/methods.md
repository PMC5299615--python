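# Methods

## The model

Genomic prediction estimates the effects of genome-wide markers in a
*discovery* sample and projects them onto a *target* sample to obtain
genetic profile scores.  The central quantity controlling how well this
works is the **effective number of chromosome segments** `Me`: the number
of independent genomic segments whose effects must effectively be
estimated.  The expected correlation between true and estimated genetic
values for a quantitative trait is

    r(g, ĝ) = sqrt( N h² b / (N h² b + Me) ),

where `N` is the discovery sample size, `h²` the heritability and
`b = M/(M + Me)` the fraction of genetic variance captured by `M`
observed markers (`b ≈ 1` for dense panels).  The phenotype-score
correlation is `h · r(g, ĝ)`.

`Me` is not a property of the genome alone — it reflects the relatedness
between discovery and target.  Under a standard neutral model the
expected squared LD correlation between loci at distance `c` Morgan is
`r² = 1/(1 + 4 Ne c)` (or `1/(2 + 4 Ne c)` with recurrent mutation), so a
smaller effective population size `Ne` means longer-range LD, fewer
independent segments, and higher accuracy at the same `N h²`.  A study
design that allows close relatives across the discovery/target boundary
behaves like a small-`Ne` population.

### Me calculators

Three routes are implemented and cross-validated:

1. **Weight solve** (`me_from_weights`): for the `M × M` matrix `S` of
   pairwise squared correlations among equally spaced SNPs, `Me` is the
   sum of the weights solving `S w = 1`.  Near-singular matrices receive
   ridge `1e-8` with a warning.
2. **Matrix mean** (`me_matrix_mean`): the approximation
   `1/Me = mean(S)`; agrees with the weight solve within 5% at
   `M = 2000` for the Toeplitz construction.
3. **Closed form** (`me_closed_form_single` / `_genome`): the
   `M → ∞` limit of the matrix mean.  For one chromosome of length `L`,

       1/Me = 2[(a + α) ln(1 + a/α) − a] / a²,  a = 4 Ne L,

   with `α = 1` (no mutation) or `α = 2` (mutation-corrected).  For
   `n` equal chromosomes, relationships at different chromosomes
   covary because drift makes a pair similarly related genome-wide;
   with between-chromosome covariance `1/(3 Ne)`,

       1/Me_genome = [ n/Me_single + n(n−1)/(3 Ne) ] / n².

   For 30 chromosomes of 1 Morgan with mutation correction this yields
   Me = 254, 1188, 4506, 10891 and 21248 at Ne = 100, 500, 2000, 5000
   and 10000.

The finite-`M` matrix sets its diagonal to 1 (a SNP is perfectly
correlated with itself).  With the mutation-corrected `r²` the closed
form corresponds to `r²(0) = 1/2`, so the finite-`M` mean carries a
diagonal excess of `(1/2)/M` relative to the limit — negligible at
`M = 5000` for small `Ne` (0.5% at Ne = 100) but ~3% at Ne = 1000; the
no-mutation construction converges cleanly.

**Empirical Me** (`me_from_grm`): given a GRM `A`, `Me` is the
reciprocal of the variance of the target × discovery off-diagonal block
entries (pooled variance with the 1/n denominator by default; a
per-target-individual average is also exposed).  Finite marker panels
add sampling variance of order `1/m` to `var(A_ij)`, biasing empirical
`Me` slightly downward when `m` is not ≫ `Me`; at the simulator's desk
scale this is a few percent.

### Case-control designs

Disease liability is standard normal; an individual is affected iff
liability exceeds the threshold `t` with upper-tail mass `K` (the
prevalence).  With cases over-sampled to a fraction `P` of the
discovery sample, the heritability on the ascertained observed scale is

    h²_01 = h² z² P(1−P) / (K² (1−K)²),

with `z = φ(t)`, and the score accuracy on the 0/1 scale is
`ρ_01 = sqrt(N h²_01 / (N h²_01 + Me))`.  The correlation between the
score and total liability is `ρ = ρ_01 · h`, and all downstream
quantities follow from truncated-normal algebra:

* **AUC** = `Φ( ρ(i − i₂) / sqrt(2 − ρ²[i(i−t) + i₂(i₂−t)]) )`, where
  `i = z/K` and `i₂ = −z/(1−K)` are the mean liabilities of cases and
  controls.
* **Percentile odds ratios**: the top fraction `q` of ranked scores has
  mean `i_q = φ(t_q)/q` and truncated variance `v_q`; its disease
  probability is approximated as
  `p_q = Φ( (ρ i_q − t) / sqrt(1 − ρ² + ρ² v_q) )`, and the odds ratio
  contrasts `p_top` against `p_bottom` or against the population odds
  `K/(1−K)`.

The within-stratum variance term `ρ² v_q` matters: dropping it inflates
the top-vs-bottom 20% contrast from ~132 to ~237 at the Ne = 100
design.  The formula is still a normal approximation to the exact
mixture integral `E[Φ((ρs − t)/sqrt(1−ρ²)) | s ∈ stratum]`; for deep
bottom strata at high accuracy it is conservative (exact asymptotic OR
≈ 154 vs 132 at the Ne = 100 design), while the top-1%-vs-population
contrast is near-exact (22.9 vs 23.0).  Simulated ORs therefore tend to
sit in the upper half of their replicate intervals.

## GBLUP

Genetic values are a random effect with covariance proportional to the
GRM; with shrinkage `λ = (1 − h²)/h²` the target scores are

    ĝ_t = G_td (G_dd + λI)⁻¹ (y_d − 1μ̂),

with the overall mean fitted by GLS, `μ̂ = (1'V⁻¹y)/(1'V⁻¹1)`.  The GLS
intercept is not cosmetic: in a case-over-ascertained discovery sample
the standardized genotype means are shifted toward risk alleles, and a
plain arithmetic centering leaves that shift in the predictor (costing
≈0.01 AUC at the Me = 254 benchmark).  The identical predictions arise
from ridge regression on standardized dosages (`snp_blup_predict`),
which serves as an exact cross-check (agreement ≤ 1e-8).

`h²` is always user-supplied (no REML).  Case-control runs use the 0/1
status as the response with `λ` from `h²_01`.  The accuracy formula is a
marginal-estimation approximation: realized BLUP accuracy exceeds it by
up to ~0.06 when `N h² ≈ Me` (BLUP pools information optimally) and
falls ~0.04 short when `m > N`; at information ratios far from 1 the
agreement is within ~0.01.

## Simulators

**Gene dropping** (`sim_genedrop`): a monoecious random-mating
population of `Ne` breeders evolves for `generations` generations; each
offspring draws two parents with replacement (selfing allowed), gametes
recombine with Poisson(`L`) crossovers at uniform positions (Haldane, no
interference), and sites mutate at `1e-8` per generation.  Founders
start every site at frequency 0.5, since at that mutation rate variation
cannot arise de novo on desk-scale timescales; `~2 Ne` generations of
drift then establish the equilibrium LD and frequency spectrum.
Discovery and target samples are freshly bred offspring of the final
generation ("expansion sampling"), so sample sizes may exceed `Ne`.
The observed genotype panel is every site with MAF > 1% (~half the
sites after `2 Ne` generations); 500 of them are causal, with
standardized effects scaled so causal variance is `h2_sim` (default
0.01, the trait architecture used for the single-chromosome validation).
Default scale: Ne = 100, 200 generations, 2000 sites on 1 Morgan,
500/250 discovery/target — one replicate runs in under a second while
leaving drift-equilibrium LD intact.  What this does *not* emulate:
realistic site-frequency spectra from mutation-drift balance, variable
recombination maps, selection, or population structure beyond a single
panmictic deme — so passing tests show the Me/accuracy theory is
internally consistent, not that real cohorts match it.

**Case-control** (`sim_casecontrol`): `m_snps` independent SNPs
(frequencies U(0.05, 0.95), HWE), normal effects scaled to `h²` on the
liability scale, normal residual, threshold at prevalence `K`.  The
discovery set reaches case fraction `P` by rejection sampling from the
prevalence-`K` population (cap 50·N/K draws); the target is an
unascertained population sample.  Setting `m_snps` to a theoretical
`Me` makes the simulation the direct stochastic twin of the analytic
chain.  Independence between SNPs is by design (it is what `Me`
*means*); LD, rare variants and covariates are out of scope.

## Validation workflows and problem sizes

`run_validation_genedrop` (20 replicates at the default config) checks
that empirical `Me` lies within 15% of the closed form and that observed
GBLUP accuracy covers the expected accuracy in its replicate 95%
interval.  `run_validation_casecontrol` (Me = 254, N = 3000, target
30000, 20 replicates) checks coverage of expected AUC and both
percentile ORs.  These sizes keep a full run in tens of seconds; the
simulators accept the original large configurations unchanged.

## Numerical choices

* Normal quantile/pdf/cdf via SciPy (machine-accurate); no custom
  approximations.
* Weight solve: symmetric solver; ridge `1e-8` + warning when the
  condition number exceeds 1e12 (perfect-LD matrices).
* GBLUP: Cholesky with diagonal jitter `1e-8`; direct solves only.
* GRM: VanRaden/GCTA column standardization with observed allele
  frequencies computed on discovery + target jointly; missing dosages
  mean-imputed per SNP; monomorphic SNPs dropped with a warning.  With
  in-sample frequencies the off-diagonal mean is `−1/(n−1)` by
  construction.
* Observed ORs from 2×2 contingency cross-products; Haldane–Anscombe
  0.5 correction on zero cells, flagged.  Rank-based AUC with half-tie
  weight.
* Relatedness pruning removes the highest-degree individual first, ties
  broken by id; percentile bins cut at `floor(n·q)` with stable tie
  order.
* `Ne·L = 0` returns `Me = 1` (one segment) rather than dividing by
  zero; degenerate strata, single-class AUC inputs and zero-variance
  GRM blocks raise errors.

## Known limitations

* The between-chromosome covariance `1/(3 Ne)` is used as given; the
  per-generation variance series it summarizes does not obviously sum
  to it, but it is what the genome-level closed form requires to match
  the multi-chromosome values above.
* Unequal chromosome lengths are supported only via the numeric
  single-chromosome path, not the genome closed form.
* The expected-accuracy formulas are approximations of order a few
  percent in the regimes documented above; they are not replicate-level
  predictions.
* h² is an input everywhere; misspecifying it shifts `λ` (mildly
  affecting realized accuracy) and the expected values (directly).
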