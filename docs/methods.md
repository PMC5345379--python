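# Methods

`morphoclade` analyses matrices of discrete morphological characters —
taxa × characters, states 0–5, `?` for missing data, parenthesised state
groups for polymorphism — under two optimality criteria, with a
synthetic-data generator that emulates the statistical structure such
matrices are assumed to have.

## The Mkv(+Γ) model

Characters evolve independently along an unrooted binary tree under a
k-state continuous-time Markov chain with equal exchange rates and a
uniform stationary distribution (the Mk model). The rate matrix is
rescaled so one unit of branch length ν is one expected character change
under stationarity. Unordered characters allow every transition; ordered
multistate characters (states forming a linear series) use an
adjacent-transition chain under the same normalisation — the package's
reading of "ordered" for likelihood, chosen for consistency with the
|i−j| step cost used in parsimony; equivalence with any particular
legacy implementation of ordered standard characters is not claimed.
Ordered and unordered coincide at k = 2, and the engine treats them so.

**Ascertainment correction.** Morphological matrices omit constant
characters, so each character's likelihood is conditioned on being
variable: `lnL_corrected = lnL − ln(1 − c)` with
`c = Σ_s Pr(every scored taxon shows state s)`, computed with the
character's own missing-data pattern (missing taxa marginalised out).
A character with no scored taxa has c = 1 and is rejected. With gamma
rate variation both numerator and c are equal-weight mixtures over the
category rates, so the conditioned probabilities of all variable patterns
still sum to exactly one (tested by enumeration).

**Rate variation.** Discrete gamma with mean-one rates, default four
equal-probability categories represented by their category means
(a category-median option exists; the default is the mean form because it
preserves the distribution's mean exactly). Shape α > 0; α → ∞ recovers
the rate-homogeneous model (tested to |ΔlnL| < 1e-6 at α = 1e6).

**Computation.** Felsenstein pruning with per-character rescaling of
partial likelihoods. Characters are stacked into blocks sharing
(k, ordered); transition matrices come from the spectral decomposition of
the symmetric rate matrix, and one flat-loop kernel (JIT-compiled with
numba when available, plain Python otherwise) evaluates a whole block per
traversal. The ascertainment terms ride along as pseudo-columns — one per
distinct missing-data mask and state — in the same traversal. Contract:
agreement with brute-force enumeration over internal-state assignments to
1e-9 on all trees of up to 5 taxa (tested), and likelihood invariance
under re-rooting (pulley principle, tested to 1e-9).

## Bayesian sampling

One cold Metropolis–Hastings chain per run (no Metropolis coupling; the
convergence criterion used here is cross-run, which single chains
preserve). State: topology, branch lengths, gamma shape. Priors: uniform
over labelled unrooted topologies; branch lengths i.i.d. exponential with
mean 0.1; shape exponential with mean 1. These are proper, weakly
informative stand-ins for the "default priors" convention of standard
Bayesian phylogenetics software, and all are configurable.

Proposals (default weights): NNI 0.4, SPR 0.1, single-branch log-scale
multiplier 0.4, shape log-scale multiplier 0.1. The multiplier
ν′ = ν·e^{λ(u−1/2)} carries Hastings factor ν′/ν. SPR detaches a uniform
subtree, merges the two edges around the old attachment (length ℓo),
picks a uniform target edge (length ℓe), and splits it at a uniform
point; the acceptance factor ℓe/ℓo is the Jacobian of that
merge-and-split map (branch-length totals and edge counts are conserved,
so the exponential prior contributes no extra term). Because the moves
are defined on a rooted *representation* of an unrooted tree, the
representation is re-canonicalised (re-hung at the internal node adjacent
to the first taxon) after every topology move; without this the SPR pair
is not an involution on the state space actually simulated. Correctness
is tested by running the sampler with the likelihood forced constant:
branch lengths reproduce the exponential prior (Kolmogorov–Smirnov) and
the three 4-taxon topologies are uniform.

A "cycle" is one proposal; draws are recorded after every `sample_every`
cycles (so `cycles // sample_every` draws; a zero-cycle run records the
start state). Runs are deterministic given their seeds.

**Convergence and run selection.** ASDSF: for every nontrivial split
reaching frequency ≥ 0.10 (configurable; the conventional cutoff) in at
least one run, the sample standard deviation of its frequency across
runs, averaged over such splits; below 0.01 is read as topological
convergence. Independent replicate analyses are compared by the
harmonic-mean estimator of the marginal likelihood, computed in log space
(log-sum-exp of −lnL); the run with the highest harmonic-mean lnL is
flagged for downstream inference. The harmonic-mean estimator is known to
be unstable in general; it is retained here as the method this pipeline
standardises on, with Bayes factors reported on the 2 ln scale and read
by the conventional banding (>10 strong).

## Clade support and its correction

PP of a clade = fraction of pooled post-burnin trees (burn-in fraction
0.25 by default, floor rounding) in which the taxon set is monophyletic
after rooting on the designated outgroup; with no wildcard taxa this
equals the frequency of the corresponding bipartition. Wildcard taxa are
pruned from each sampled tree before testing. A clade seen zero times is
reported as "< 1/n_samples" rather than 0. The majority-rule consensus
contains exactly the splits with frequency > 0.5 (strictly greater), each
labelled with its frequency, with branch lengths averaged over supporting
trees.

Because PP is liberal for clades subtended by short branches (below
roughly 35 expected character changes), credibility verdicts pass through
a monotone lookup: minimum PP accepted as ≥95% credible, as a step
function of branch length (posterior-mean ν on the subtending edge ×
number of included characters). At ≥35 changes the plain 0.95 cutoff
applies. The shipped default table — 0.99 below 15 changes, 0.98 to 25,
0.97 to 35 — is an explicit approximate stand-in anchored to two usable
calibration points (PP 1.00 at 28.2 changes passes; PP 0.96 at any
shorter length fails); users substitute their preferred table via a TSV.

## Parsimony

Unordered characters are scored by the Fitch set algorithm (bitmask
vectorised across characters), ordered characters by Sankoff dynamic
programming with cost |i−j|; ambiguity sets resolve to whichever state
minimises length, so missing data costs nothing. Per-character minima for
the consistency index: smallest hitting-set size minus one (unordered) or
narrowest covering interval (ordered), exact for k ≤ 6. CI = Σ m_c / L.
Parsimony informativeness requires two states each seen unambiguously
(singleton cells only — the conservative reading) in two or more taxa.

Search: random-order stepwise addition (greedy best insertion, ties
broken randomly) followed by branch swapping to completion, retaining all
equally short trees up to maxtrees (auto-growing by 100, PAUP-style, with
a configurable cap). The default swapper is TBR, implemented as SPR
neighbourhoods augmented with re-rootings of the pruned subtree; plain
SPR and NNI are available. On 6–8-taxon fixtures the heuristic always
matches exhaustive search over all topologies (tested on 50 seeded
matrices).

Bootstrap resamples included characters with replacement and scores each
split by the percentage of replicates whose MPT strict consensus contains
it (the replicate-consensus convention; frequency-within-MPT-pool is the
documented alternative). Bremer decay is the length excess of the
shortest tree lacking the split, by exhaustive evaluation up to 8 taxa
and reverse-constraint heuristic search (trees containing the split
scored as inadmissible) above.

## Synthetic data

The generator emulates the assumed generating process, not any real
matrix: pure-birth (Yule) topologies with branch lengths rescaled to a
requested mean root-to-tip depth (in expected changes per character);
discrete characters drawn with a k-distribution matching the shape of a
typical morphological character list (~3/4 binary), a configurable
fraction of multistate characters ordered, per-character gamma rates,
uniform root states, and rejection of constant characters when
`variable_only` is set — the empirical conditioned pattern frequencies
match the Mkv likelihood's analytic values (tested at 3 standard errors
on 50,000 characters). Missing data and two-state polymorphism sets are
injected independently per cell at configurable rates (on binary
characters an injected polymorphism is indistinguishable from missing).
Quantitative traits follow Brownian motion, feeding the median
binarization. A fixed metadata fixture reproduces the bookkeeping of a
real 163-character study list (27 quantitative, ordered set of 13,
4 exclusions, per-character state counts).

What the generator does *not* emulate: correlation between characters,
clock-like or empirically shaped trees, taxon-dependent missingness
(missing data in real matrices concentrates in poorly preserved taxa),
or coding error. Passing recovery tests therefore demonstrate sampler
and scorer correctness under the assumed model, not robustness to
model violation.

**Problem sizes.** The shipped test battery and the acceptance script
use 4–20 taxa and 10–300 characters, 100,000-cycle chains for the
20-taxon recovery experiment, and exhaustive parsimony up to 8 taxa
(10,395 topologies) — sizes at which every stochastic check has an exact
or enumerative counterpart. The recovery experiment simulates at tree
depth 0.7: deep enough that internal branches of ≥0.3 expected changes
exist, shallow enough that characters are not saturated — at depth 1.0
multiple hits on pendant edges make even well-subtended cherries
genuinely ambiguous in the posterior, which tests the data rather than
the sampler.

## Numerical and design notes

* Per-character state count k defaults to the states observed in the
  matrix (the "standard data" convention); metadata can override it.
* Median binarization puts values equal to the median in state 0
  (configurable); the median of an even count is the midpoint of the
  central order statistics. Missing measurements are excluded from the
  median, not imputed. Majority-coding ties are kept as polymorphism.
* NEXUS I/O targets the MrBayes-compatible subset (symbols 0–9,
  `missing=?`, `gap=-`, gap treated as missing); `ctype`/`exset`
  commands in an ASSUMPTIONS block carry ordered/excluded flags, and two
  benign annotations (a `charset quantitative` and a `[KMAX ...]`
  comment) let a written file round-trip its full metadata while staying
  readable by standard programs. Character indices are 1-based
  everywhere a user sees them.
* Excluded characters keep their numbers and contribute exactly zero to
  every likelihood and parsimony computation (tested against physical
  column deletion).
* Zero-length branches are proposal-safe (lengths are floored at 1e-12
  inside multiplier and SPR moves only, never in the recorded state).
* The taxon ordering for bipartition bitmasks is the matrix row order;
  masks are normalised to the side not containing the first taxon.

## Known limitations

* The harmonic-mean marginal-likelihood estimator has infinite variance
  in theory; stepping-stone estimation is out of scope.
* Single-chain runs can mix slowly on large or conflicted matrices; the
  ASDSF diagnostic reports, but does not repair, poor convergence.
* The branch-length correction table is an approximate stand-in, not a
  reproduction of the published original.
* Heuristic parsimony guarantees optimality only where exhaustive search
  is feasible; above that it shares the usual local-optimum caveats.
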