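# Methods

## The IBS hierarchy and G*-statistics

The package describes population structure through non-identity-by-state
(non-IBS) probabilities. For an ordered hierarchy of sampling levels
0, …, L (level 0 = the two gametes that united to form a random
individual; level 1 = two genes from one deme; level 2 = two genes from
the metapopulation), `h_i` is the probability that a level-`i` pair
belongs to different allelic classes. The association at level i is
G_i* = (h_i − h_{i−1})/h_i, so 1 − G_i* = h_{i−1}/h_i and the product over
levels telescopes to 1 − G_IT* = h_0/h_L. G_i* ≤ 1 always; G_i* < 0
exactly when diversity at level i is *lower* than at the level below, a
meaningful state of affairs (see the two-deme model) that the code never
clamps away.

For the island model the three levels are assembled from the identity
triple (f, g_w, g_b) — IBS of uniting gametes, of genes in distinct
same-deme individuals, and of genes in distinct demes — by the exact
finite-N/finite-d forms

    h_0 = 1 − f
    h_1 = [(1 + f)/2]/N + (1 − g_w)(1 − 1/N)
    h_2 = h_1/d + (1 − g_b)(1 − 1/d).

The 1/N and 1/d terms are the probabilities that a "without regard to
structure" pair lands in one individual or one deme. These are the
formulas the estimators and solvers use verbatim; their O(1/N) residue
(e.g. h_1 = 1/N rather than 0 for a fully monomorphic population) is
intentional — the large-N indices G_IS*, G_ST* are recovered as limits,
and all asymptotic statements in the tests carry an explicit c/N bound.

Classical partition arithmetic: F_ST = G_w (the correlation among uniting
gametes after one hypothetical generation of random mating equals the
correlation between random gametes), F_IS = (F_IT − G_w)/(1 − G_w), and
1 − F_IT = (1 − F_IS)(1 − F_ST) holds identically.

Pedigree inbreeding uses the standard tabular kinship recursion
(φ(a,a) = (1 + F_a)/2, φ(a,b) = [φ(a, sire_b) + φ(a, dam_b)]/2 in
topological order), with founders — individuals with no recorded
parents — non-inbred and mutually unrelated. The recursion is equivalent
to Wright's path counting but robust to overlapping inbreeding loops; a
gene-dropping Monte Carlo in the test suite confirms it on a looped
8-member pedigree.

## Island model with partial selfing and K-allele mutation

d demes of N diploid reproductives. Each offspring draws a parental deme
(its own with probability 1 − m, each other deme with probability
m/(d − 1)), a mother uniformly within it, and a father who is the mother
with probability s, otherwise a uniform draw from the deme (which still
hits the mother with probability 1/N). Hence the uniparental probability
is σ = s + (1 − s)/N. Each transmitted gene mutates with probability u,
moving to one of K − 1 other allelic classes uniformly; K = ∞ is an exact
infinite-alleles flag (every mutation novel), not a large-K approximation.

The pair-identity recursion is affine in (f, g_w, g_b). With
ψ = (1 − m)² + m²/(d − 1) and χ = 2m(1 − m)/(d − 1) + m²(d − 2)/(d − 1)²
(probabilities that a together/apart pair of lineages finds itself in one
parental deme), and w = (1/N)(1 + f)/2 + (1 − 1/N) g_w:

    f'   = a( σ (1 + f)/2 + (1 − σ) g_w )
    g_w' = a( ψ w + (1 − ψ) g_b )
    g_b' = a( χ w + (1 − χ) g_b )

where a(g) = A g + B (1 − g) applies one generation of mutation on both
lineages, A = (1 − u)² + u²/(K − 1), B = 2u(1 − u)/(K − 1) +
u²(K − 2)/(K − 1)² (A = (1 − u)², B = 0 for infinite alleles). The f-row's
biparental branch is g_w directly, because a biparental egg–sperm pair is
one random gene each from two distinct residents of one deme — the
defining g_w configuration; this makes the map the exact one-generation
law of the forward simulator, which the Monte Carlo suite verifies. The
steady state is the unique fixed point for u ∈ (0, 1), obtained by one
3×3 linear solve (u = 0 returns the all-ones fixation state). d = 1 is
supported with m forced to 0.

Selfing feeds the within-individual resolution process: a pair of
lineages in one individual coalesces (probability 1/2 per uniparental
generation) or escapes to distinct individuals, resolving to outcross
with probability (1 − σ)/(1 − σ/2). This yields N_e = N(1 − s/2) and the
relative coalescence rate Δ = 1/(1 − s/2) ∈ [1, 2], which carries the
entire effect of selfing in the closed form

    G_ST* = Δ / (Δ + [d/(d−1)] (M d/(d−1) + θ K/(K−1))),   M = 4Nm, θ = 4Nu.

The K/(K − 1) factor weights mutation more heavily when fewer allelic
classes exist (at K = 4 it is 4/3 of the infinite-alleles value), because
back-mutation then creates IBS without IBD. The solver approaches this
form and G_IS* = (s/2)/(1 − s/2) with error ≤ c/N, c ≈ 2.6 empirically
(bound c = 10 asserted), halving as N doubles.

## Asymmetric two-deme model

Two demes hold shares r and 1 − r of the reproductives (N = average deme
size); scaled migration rates M_i = 4N m_i, scaled mutation θ = 4Nu. In
coalescent time units of 2N generations a pair of lineages coalesces at
rate 1/(2r) when both sit in deme 0, 1/(2(1 − r)) in deme 1; each lineage
migrates at rate M_i/2; mutation strikes the pair at rate θ. Identity is
P(coalescence before any mutation) — the infinite-alleles reading, which
is what makes the closed-form threshold below exact. First-step analysis
over the three pair states (W0, W1, B) gives a 3×3 linear system for
(g_w0, g_w1, g_b); θ = 0 returns all ones, and M0 = M1 = 0 returns
g_b = 0 with a warning (isolated demes never coalesce).

Deme-specific indices β_WT0 = (g_w0 − g_b)/(1 − g_b) and
G_ST,0* = (1 − r)(g_w0 − g_b)/[r(1 − g_w0) + (1 − r)(1 − g_b)] share their
sign and satisfy |β_WT0| ≥ |G_ST,0*|; both are negative iff g_b > g_w0,
which requires r > r_min = [1 + M0 + 2(M1 + θ)]/[2(M0 + M1 + θ)] — always
above 1/2, unattainable unless M0 > 1, and decreasing in M0 (*soft
migration*: migrant numbers unconstrained by deme size). Under *hard
migration* (N0 m0 = N1 m1, i.e. r M0 = (1 − r) M1) the threshold is never
crossed and both indices stay non-negative. The test suite confirms the
threshold against the solver by bisection to 1e−8.

Expected coalescence times solve the same chain with θ = 0 and unit time
accumulation. Population-wide sampling draws two individuals uniformly
from the metapopulation: pair weights r², (1 − r)², 2r(1 − r), with E(Ts)
conditioning on cohabitation. Slatkin's F_ST* = (E(T) − E(Ts))/E(T); the
identity-based G-analog converges to it as θ → 0 (verified by a
finite-difference ladder over θ = 1e−2 … 1e−4). The IBS analog of Nei's
distance, D* = −½[ln(g_b/g_w0) + ln(g_b/g_w1)], is strictly positive at
every steady state of this model even where the deme-specific indices are
negative. Raw migration rates above 0.15 per generation violate the
separation-of-timescales assumption behind the scaling (rates of order
1/N) and trigger a warning rather than an error.

## Simulators (the independent oracles)

*Forward Wright–Fisher*: the generation law above, simulated for every
gene in the metapopulation with numpy-vectorized parent assignment.
(f, g_w, g_b) are read off sampled states exhaustively via per-deme
allele-class counts (all cross-individual ordered gene pairs — an
average over each pair's four gene comparisons, matching the estimator
definition). Standard errors come from means of independent replicate
populations, so within-run autocorrelation cannot deflate them.
Defaults: burn-in 20·(2Nd) generations; a warning fires when the first
and second halves of the sampling window differ by more than 2 SE.

*Backward pair samplers*: two lineages traced through the same generation
structure. For the island model the embedded jump chain over states
{same individual, same deme, different demes, coalesced} is simulated
with geometric sojourn-skipping, accumulating Binomial(2t, u) mutation
events per sojourn; the identity indicator is Rao-Blackwellized through
P(IBS | n mutations) = 1/K + (1 − 1/K)(−1/(K − 1))ⁿ (0ⁿ for infinite
alleles). For the two-deme model the continuous-time race among
coalescence, migration and mutation is simulated directly. Both samplers
are vectorized across replicates and exact realizations of their models —
no time discretization error beyond the models' own.

*Synthetic genotypes*: loci are read from stationary forward states
separated by 2Nd generations (several within-deme coalescent times, so
loci are approximately independent replicates — exactly what the
multilocus estimator theory assumes; real linked loci would be
positively correlated across the genome, which these tables do not
emulate, so the estimator tests validate point estimates, not
between-locus covariance). Individuals are drawn without replacement per
deme, independently per locus. All samplers draw from a single seeded
generator; runs are bit-reproducible from (config, seed).

## Estimators

Plug-in analogs of the parameters: f̂ = proportion of homozygotes; ĝ_w =
mean allele-match over all pairs of distinct individuals within a deme
(each pair contributing the mean of its four cross-gene comparisons),
demes weighted equally as in the exchangeable island model; ĝ_b = the
same over cross-deme pairs. Missing genotypes are excluded pairwise;
statistics that lack data (a deme with < 2 callable individuals, a single
deme for ĝ_b) are reported as missing, never as zero. No small-sample
bias correction is applied — the estimands are the model's identity
probabilities. Multilocus combination averages h-levels across loci
before forming ratios (ratio of averages); per-locus values are emitted
alongside so average-of-ratios users can roll their own. The 1/N in h_1
refers to the census deme size: when the sample is not the census, pass
the census override. VCF sites are treated as independent loci with
allele indices as classes; no LD pruning is attempted (document-level
user responsibility). Fully monomorphic input raises an error — there is
no variation to partition.

## Problem sizes and numerical choices

Floating tolerances: partition identities are exact to 1e−12 (all
quantities O(1) probabilities); the r_min bisection runs to 1e−10 and is
compared to the closed form at 1e−8. The steady-state linear systems are
well-conditioned for u ∈ (0, 1) (diagonally dominant after the mutation
contraction); solutions are clipped to [0, 1] only against ≤1e−9
round-off excursions.

The stochastic cross-validation suite runs the forward simulator at
N = 50, d = 5 over eight (s, K, Nu = Nm) combinations with 16 replicate
populations × 50 sampled states each (burn-in 4,000 generations, samples
100 generations apart), comparing each of f, g_w, g_b to the analytic
steady state at 3 replicate-level standard errors; the suite completes in
about a minute. Backward-sampler checks use 4×10⁴–2×10⁵ pair replicates.
These sizes were chosen so replicate-level t-noise sits well below the
3 SE criterion while the full test suite stays desk-scale.

## Known limitations

* Mutation models beyond K-allele/infinite-alleles (stepwise, finite
  sites) are out of scope, as are selection, extinction–recolonization,
  and non-equilibrium dynamics.
* The two-deme machinery does not generalize to d > 2 asymmetric demes
  (the island model covers the symmetric case).
* Estimator uncertainty (jackknife/bootstrap over loci) is not provided;
  per-locus outputs make it easy to add externally.
* The equality N_e = N̄ sometimes quoted for unequal-deme models depends
  on a sampling convention the package does not fix; it reports the
  pair-process quantities and leaves that identity alone.
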