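# Methods

## The statistical problem

Recombination hotspots are narrow (~2 kb) intervals where the
population-scaled recombination rate ρ = 4N_e r is many-fold above the
local background.  Direct measurement of fine-scale recombination is
impractical in most species, but hotspots leave a footprint in linkage
disequilibrium (LD): allelic associations decay faster across a hotspot
than its physical width suggests.  This package detects that footprint
in a sample of n phased haplotypes, and quantifies — by simulation —
how well the detection protocols actually work.

## Composite likelihood and the test statistic

For two biallelic SNPs separated by scaled distance ρ, the two-locus
sampling probability lik(s_i, s_j | ρ) is the chance of the observed
two-locus haplotype counts under the neutral coalescent with
recombination.  The composite log-likelihood of a window is the sum of
log lik over all unordered SNP pairs — pairs are treated as independent,
which they are not, so the result is not a true likelihood; it is
nevertheless a workable objective for estimation and, with simulation
calibration, for testing.

Two nested models are fitted to each analysis window of X kb:

* constant: one rate ρ per kb everywhere;
* hotspot: background ρ0 per kb, elevated to ρ1 per kb inside the
  central 2 kb test interval.

The statistic is Λ = 2 ln R, the log-ratio of the maximized composite
likelihoods.  Both maximizations are exhaustive grid searches; because
the constant grid is a subset of both hotspot grids, Λ ≥ 0 holds
exactly, not approximately.  ρ1 is deliberately *not* constrained to
exceed ρ0.  The distance a model puts between two sites is the
piecewise-linear integral of its per-kb rate over the physical
separation, and every SNP pair in the window contributes (no distance
cap by default; one can be configured for speed).

Default grids: ρ0 (and the constant model) on 15 points from 0 to 5/kb,
dense at low rates where background estimates live; ρ1 on those points
plus 9 more up to 100/kb.  Grid maxima must stay comfortably inside the
two-locus table's ρ grid (max 500) for the widest pair span used.

## Two-locus tables

lik(s_i, s_j | ρ) is precomputed by Monte Carlo in the θ→0 limit: for
each ρ on a 17-point grid (0 to 500, dense below 10), simulate two-locus
genealogies (msprime, two discrete loci with recombination only between
them), place exactly one mutation on each locus's marginal tree with
probability proportional to branch length, and tally the resulting
haplotype-count configurations.  Conditioning on one mutation per locus
removes θ from the table and matches the classical two-site likelihood
construction.  Configurations are folded to a canonical form (lex-max
over allele flips at either locus and locus exchange) since the
sampling distribution shares those symmetries.

Between grid points the log-probability is interpolated linearly in ρ;
above the grid maximum it clamps.  Configurations never observed at
some grid point get a floor probability of 0.5/reps instead of zero, so
one rare pair cannot send a whole window to −∞; consequently the
stored column mass is exactly 1 (observed counts) plus a small known
floor excess.  Tables are keyed by (n, grid, reps, seed) and refuse
mismatched lookups.

## Null distribution and conditional p-values

Λ has no analytic null distribution.  Following the lookup-table
scheme, many constant-rate X-kb windows are simulated in advance over a
uniform mixture of (θ, ρ) — default θ ∈ {0.5,1,2,5} × ρ ∈
{0.1,0.2,0.5,1,2.5,5} per kb — recording (Λ, S, ρ̂) for each: the test
statistic of the central 2 kb, the segregating-site count, and the
constant-rate composite estimate.  An observed window is then compared
only against null records with similar S (bins of width max(2, 5% of
the typical null S)) and similar ρ̂ (deciles of the null ρ̂
distribution), via the add-one estimator p = (1 + #{Λ_null ≥ Λ_obs}) /
(m + 1).  Bins widen symmetrically until they hold at least
`min_bin_count` records (default 500), so sparse corners degrade toward
the marginal null instead of failing.

A real feature of the grid LRT: Λ has a point mass at exactly 0 from
boundary solutions — windows whose data show no usable recombination
signal, where both models maximize at rate 0.  Such windows receive
p = 1, which is conservative and harmless for calling, but it means the
p-value distribution is exactly uniform only where that atom is
negligible.  At the headline study scale (n = 30, X = 20 kb, mixture
rates ≥ 0.1/kb) the atom is vanishingly small.  The calibration test in
the suite runs a scaled-down configuration (n = 10, X = 6 kb, θ = 2/kb,
generation ρ ∈ {2.5, 5}/kb, 1e5-record archive) chosen so that the
atom stays below ~1%; its ρ1 grid also includes each background rate
±0.01 so that near-diagonal maxima register as Λ > 0 rather than tying.

## Scanning and the three calling protocols

Every 2 kb window (1 kb step) of a region is tested inside an X-kb
analysis window centered on it (truncated at region edges).  Windows
with p < 0.01 have their 2 kb extents merged (abutment counts as
overlap) into candidate regions, then:

* **auton2012** (200 kb windows originally): drop candidates > 5 kb long
  or whose peak per-kb rate profile is below 5/kb;
* **auton2014** (100 kb originally): keep a candidate, in full, iff it
  contains a window with p < 0.001; no other filter;
* **mlehot** (20 kb): cut candidates into 1 kb tiles anchored at
  coordinate 0; keep tiles whose rate profile is ≥ 5/kb (or ≥ 10× the
  background rate, for the sensitivity analyses); merge adjacent
  survivors.

The per-kb rate profile stands in for an external variable-rate LD map:
entry k is the profiled hotspot-rate estimate ρ̂1 of the 2 kb window
centered on tile k, fitted with 9 kb of flanking context on each side.
This is a documented deviation — the original protocols used a separate
reversible-jump MCMC rate estimator — and shifts the absolute power of
the rate-filtered protocols by an unknown amount; trends across folds
and window sizes are unaffected in kind.  Tiles whose context holds
fewer than two SNPs get profile value 0 (no estimate exists; 0 is
conservative since such a tile can never pass a rate filter).

## The simulation study

Study regions reproduce the published design: 1 Mb, background
ρ = 0.5/kb, eight 2 kb hotspots at 10/20/50/100-fold over background
(two per intensity, order shuffled per replicate), sampled as n = 30
haploid sequences at θ = 1/kb.  Hotspot centers are evenly spaced
(106.25 kb, 218.75 kb, … for the default geometry) — placement is a
design choice here; even spacing avoids edge effects and
inter-hotspot interference.  Accuracy is measured in base pairs:
power = called ∩ true / true, FPR = called \ true / non-true,
FDR = called \ true / called, pooled over replicates (bp counts are
summed before ratios are formed, so the pooled value equals the value
on the concatenated regions).  FDR with zero called bp is reported as 0
with a flag, keeping aggregation total.

Simulation uses msprime with ploidy 1 and population size 1 so one
simulation time unit is one coalescent unit: per-bp rates of ρ/2000 and
θ/2000 give scaled per-kb rates of ρ and θ, verified against
Watterson's E[S] = θ_tot Σ 1/i in the suite.  Infinite-sites mutations
are floored to integer bp (collisions jittered to the next free
integer); monomorphic and non-biallelic columns are dropped.  All
randomness derives from a single root seed via (root, replicate,
purpose-tag) hashing, so any replicate is replayable in isolation.

What the generator does *not* emulate: demographic history, selection,
gene conversion, mutation-rate variation, genotyping error, phasing
error, and missing data.  Passing tests therefore certify the method's
behavior under its own model assumptions, not its robustness on real
data.

## Problem sizes used by the checked runs

Full production scale (100 × 1 Mb regions, ~5e6-record null archives)
is supported through configuration but is a cluster-sized job.  The
shipped experiments use: two-locus tables of 3e3–2e4 replicates per
grid point (the larger count for the reproduction script — table
Monte-Carlo noise inflates null Λ tails and so deflates power, making
table size the single most power-relevant knob at desk scale); null
archives of 8e2–2e4 records (1e5 for the calibration experiment),
generated at the study's θ = 1/kb for the reproduction script since
conditioning on (S, ρ̂) makes the generation mixture irrelevant in
principle and concentrating records buys conditioning resolution;
10 × 1 Mb regions for the script's study (20 hotspots per intensity);
20 × 200 kb regions at window sizes 20 and 50 kb for the ordering
checks.  With the reduced archives the auton2014 p < 0.001 retention
rule is only resolvable when bin occupancy is ≥ 1000, which the
script's archive guarantees.

## Known limitations

* Composite likelihood ignores pair dependence; Λ magnitudes are only
  meaningful against the simulated null, never against chi-square.
* The ρ profile stand-in makes absolute power of auton2012/mlehot
  protocols not directly comparable to runs using an external LD map.
  In particular, the profiled argmax ρ̂1 has a heavy upper tail: on
  constant-rate data (ρ = 0.5/kb) about 10% of 1 kb tiles exceed the
  5/kb filter threshold (measured over 40 simulated regions), which
  inflates the rate-filtered protocols' FDR relative to a smoother
  posterior-mean rate map.
* Monte-Carlo tables at desk-scale replicate counts put a floor of
  ~1e-4 on pair probabilities; very rare configurations are noisy.
* The null archive conditions on (S, ρ̂) marginally per window;
  correlation between overlapping scan windows is not modeled (the
  published protocols share this property).
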