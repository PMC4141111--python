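# Methods

## The mapping problem

A radiation hybrid (RH) panel is a set of hybrid cell clones, each of which
carries a random sample of irradiation-induced fragments of a donor genome
on a host-cell background. Two markers that sit close together on a
chromosome are usually retained or lost together; markers far apart are
retained nearly independently. Scoring each clone for the presence or
absence of many markers therefore measures marker proximity, and an ordered
map can be estimated together with inter-marker "breakage" probabilities.
Distances are expressed in centiRays: d = −100·ln(1−θ) for breakage
probability θ, so 1 cR is a 1% chance of at least one break between two
markers. At the panel's radiation dose, 1 cR corresponds to roughly 32.6 kb,
which sets the map's physical resolution.

`rhmap` implements the full chain from raw cross-species SNP-array
intensities to robust chromosome maps, an updated scaffold assembly (AGP),
and synteny breakpoint reports, plus a truth-tagged simulator that makes
every stage testable without panel data.

## Genotype calling from an empirical null

Cross-species genotyping has a built-in control: a sizeable subset of array
SNPs has no conserved target in the donor genome and yields background
intensity in every sample, including a whole-genome positive-control DNA.
Those **negative SNPs** provide, within each clone, an empirical null
distribution of the calling statistic Imax (the larger of the two allele
intensities). The p-value that a SNP is *not* retained in a clone is the
fraction of that clone's negative-SNP Imax values strictly exceeding the
observed Imax, floored at 1/Nneg when none exceeds it.

Storey q-values convert these p-values to FDR-calibrated calls:
q ≤ 1% → retained; an intermediate band (q below 10% for the sheep-type
array, 5% for the cattle-type array) → missing; larger q → not retained.
The null-proportion estimate π0 doubles as 1 − (panel retention fraction).
Two π0 modes are provided: the λ-grid smoother (default, mirroring the
reference q-value procedure) and a fixed λ = 0.5 single-point estimator for
bit-reproducible tests. QC then removes SNPs whose retention falls outside
(10%, 50%) and clones retaining more than 90% of markers.

Numerical notes:

- Negative SNPs are found by a kernel-density antimode of the control-sample
  log-Imax; if the density is unimodal, a low-quantile fallback (default 5%)
  is used with a warning.
- "Exceeds" is strict; ties count as non-exceeding.
- The 1/Nneg floor must lie below the q ≤ 1% band for retained calls to be
  possible at all. The real arrays carry thousands of negative SNPs; any
  scaled-down simulation must therefore keep the negative-SNP *count* (not
  fraction) at a few hundred or more. The built-in fixtures do this
  explicitly.

## Retention-chain likelihoods

Along an ordered set of markers, retention in one clone follows a two-state
Markov chain: with probability θ_k a break falls in interval k, and every
fragment is retained independently with probability r:

    P(S₁=1) = r,   P(S_{k+1}=1 | S_k=1) = (1−θ_k) + θ_k·r,
                   P(S_{k+1}=1 | S_k=0) = θ_k·r.

The **diploid equal-retention model** runs two independent copies of this
chain with shared (r, θ) and observes the OR of the two states — donor
cells are diploid. An explicit emission layer (false-negative probability
`eps_fn`, false-positive `eps_fp`; `RHModelParams` defaults 0.05/0.005,
settable to 0 for the exact textbook chain) sits on top; missing
observations are marginalised, never imputed. Likelihoods use a scaled
forward algorithm (2 states haploid, 4 joint states diploid) and are checked
against brute-force enumeration over hidden state paths in the test suite.

**Two-point estimation** maximises the haploid 2-marker likelihood — a
closed form over the 9 observable cell types — on a (θ, r) grid (θ step
0.01) with golden-section refinement, ties toward smaller θ. The linkage
LOD compares the fitted model with independence (θ = 1, retention
re-maximised). Pairs with fewer than 10 doubly informative clones are
declared unlinked.

**Multipoint EM.** The chain is augmented with per-interval breakpoint
indicators and per-fragment retention draws, giving closed-form M-steps:
θ_k is the posterior mean breakpoint count per clone-copy in interval k, and
r is the posterior fraction of fragment starts (initial fragment plus one
per breakpoint, per copy) that were retained. E-steps use forward–backward;
convergence is a log-likelihood improvement below 1e−9 (the tolerance used
for the published maps), capped at 2000 iterations. Final map distances
always come from the diploid equal-retention fit; retention is fitted per
linkage group.

At ~90 clones an individual interval θ carries appreciable sampling noise,
and because d(θ) is convex, summed map lengths inflate by roughly 10–20% in
single replicates; recovery within ±15% is assessed on replicate averages
at 200 clones.

**Where the error channel operates.** Genotyping errors that the chain must
explain as breakpoints inflate distances severely (a 5% false-negative rate
triples the fitted length of a dense map if ε = 0). The pipeline therefore
runs its EM fits and ordering geometry with a *light* channel
(ε_fn = 0.01, ε_fp = 0.001, the map-builder defaults), which removes almost
all of that inflation while barely touching clean-data geometry. A heavier
channel (0.05) is deliberately *not* used inside ordering and the MCMC: it
absorbs the co-retention signal of close marker pairs, flattening the order
posterior on clean data — order uncertainty caused by genotyping error is
meant to surface as robust-map removals, not to be explained away. The MCMC
distance matrix is computed from the pure chain (ε = 0) for the same
reason.

## Map construction

1. **Linkage groups**: single-linkage connected components at two-point
   LOD ≥ 10. Components below 5 markers are dissolved and their markers
   reported unlinked (automating the manual raising of the LOD threshold).
2. **Chromosome assignment**: majority vote over members' reference-assembly
   chromosomes, ties broken lexicographically and reported.
3. **Ordering**: the group becomes a travelling-salesman *path* over
   two-point cR distances (unlinked pairs capped at 300 cR, beyond panel
   resolution). Greedy nearest-neighbour tours from multiple starts are
   improved by 2-opt and single-marker reinsertion, then polished by
   hill-climbing on the **comparative score**: the multipoint log-likelihood
   minus λ per breakpoint against the reference assembly order. Breakpoints
   between the RH order and the assembly order are treated as rare Poisson
   events; λ defaults to 3 natural-log units (prior odds ≈ 20:1 against
   each breakpoint — the source pipeline does not print its value, so it is
   exposed in configuration). The data overrule the prior exactly when they
   are informative enough, which is the property that lets the maps correct
   assembly errors.
4. **Error flagging**: for each non-missing call, the log10 ratio of the
   full-data likelihood with that single call flipped versus as-observed,
   from one forward–backward pass. The ratio is evaluated under the pure
   retention chain (an emission-error channel would cap it at (1−ε)/ε and
   make the 1000:1 criterion unreachable); θ values are floored at 1e−6 so a
   flip is never literally impossible. Cells at ratio ≥ 3 (1000:1) are set
   to missing. Order → EM → flag iterates at most 3 rounds.
5. **Long terminal intervals**: markers hanging at map ends across gaps
   longer than 25 cR are dropped and reported, automating the published
   manual end-trimming.

## Robust maps

A Metropolis–Hastings chain over marker orders targets
exp(comparative score), starting from the LKH map. Markers whose vectors
agree wherever both are non-missing (zero obligate breakpoints) are first
collapsed into position bins — the data cannot order them. Proposals mix
segment reversal (0.5), single-bin reinsertion (0.3) and short-segment
translocation (0.2), all symmetric; per-interval θ values for a proposed
order are read off the two-point distance matrix rather than refitted, which
keeps each iteration O(markers × clones). 5000 iterations with 1000 burn-in
(the published run lengths); an order and its reversal count as one state,
since RH data cannot orient a chromosome.

The **robust map** is extracted by greedy deletion: while the most frequent
relative order of the remaining bins has posterior mass below 95%, remove
the bin whose removal most increases that mass (ties: lowest mean adjacency
stability). The published inclusion-tree summarisation is not specified in
enough detail to reproduce; greedy deletion honours the same contract —
every reported order relation holds with ≥ 95% posterior mass — and is the
documented simplification here. The map-LOD diagnostic is the log10 ratio of
best to second-best posterior order mass. Final distances come from a
diploid equal-retention EM fit on the robust order at tolerance 1e−9, with
orientation anchored to the reference order.

## Scaffold anchoring

Conflicts between maps follow a fixed priority: scaffolds (never split) >
RH map > super-scaffolds > comparator-genome synteny. Per scaffold:

- markers vote on the chromosome (majority; ties flagged);
- an IQR filter (Tukey hinges — median-of-halves with the median included
  for odd n, fixed for cross-implementation determinism — 1.5×IQR fences)
  discards suspicious marker positions;
- the median kept-marker cR ranks the scaffold along the chromosome; within
  runs of scaffolds whose cR spans overlap (indistinguishable to the map),
  super-scaffold internal order is preserved;
- orientation is the sign of the OLS slope of map position on scaffold
  coordinate, declared unknown when the slope is not significantly non-zero
  (two-sided t-test at α = 0.05 — "close to 0" is not quantified in the
  source, so a standard test operationalises it); one- or two-marker
  scaffolds are never oriented by the map; unknown orientations fall back to
  comparator synteny, with provenance recorded.

Unplaced scaffolds shorter than 10 kb are excluded. Others are assigned a
chromosome by their strongest two-point linkage to mapped markers (LOD ≥ 10
required) and inserted only between two contiguous placed scaffolds, next to
the best-linked marker's position. The result serialises as AGP 2.0 with
100 bp type-U "map" gaps (gap conventions are a package choice); an AGP
parser provides lossless round-trips.

## Synteny comparison

With each marker carrying coordinates on map A and comparator genome B,
blocks grow along A-order while the B chromosome is unchanged and the B-rank
steps ±1 consistently with the block's orientation, tolerating up to one
isolated outlier (recorded as noise); runs below 3 markers fold into noise.
Both defaults are configurable — the source does not state its tolerances.
Adjacent blocks define breakpoint records classed as inversion (orientation
flip), inter-chromosomal exchange (B chromosome change — the class that
captures Robertsonian fusions) or intra-chromosomal transposition (rank
jump). Reports print Mb to two decimals; full precision is kept in the
tables.

## The simulator

`rhmap.simulate` generates every input the pipeline consumes, with ground
truth attached:

- **Fragmentation**: homogeneous Poisson breakage at `cr_per_bp/100` breaks
  per bp (default 1/32,600 cR per bp), two independent haploid copies per
  clone — exactly the chain the likelihood assumes. Fragment retention is
  Bernoulli(r); diploid marker retention is 1−(1−r)², so r ≈ 0.194 yields
  the 35% panel regime.
- **Selection**: a fragment overlapping a selection locus (the
  thymidine-kinase analogue at the panel's selectable marker) is kept with
  probability max(r, peak·exp(−distance/decay)). The decay form is a
  stand-in — the source shows the retention profile only graphically — and
  produces the expected near-100% retention at the locus, decaying over the
  fragment-length scale.
- **Observation noise**: false-negative flips (regime 5–7%), optional false
  positives, and missing masking (~5%), applied after the OR of the two
  copies.
- **Intensities**: two log-normal classes on the log scale (background
  μ=−1.5, retained μ=1.0, σ=0.4 — the source shows only a qualitative
  bimodal mixture), a designated negative-SNP subset that is background in
  every sample, and positive/negative control samples.
- **Comparators and scaffolds**: implanted inversions, reciprocal
  translocations and Robertsonian fusions with recorded junction flanks
  (each junction flanked by ≥ 3 markers so implanted truth is detectable at
  the default block size); chromosome partitions into scaffolds at
  marker-free points with shuffled, inverted and withheld subsets and a full
  truth table.

What the simulator does **not** emulate: scanner batch effects, locus-
specific hybridisation efficiency, chimeric scaffolds, segmental
duplications, or sequence-level breakpoints. Passing tests demonstrate the
statistical machinery under the model's own assumptions plus the stated
noise regimes, not robustness to artefacts outside the model.

## Problem sizes and determinism

Test and acceptance runs use scaled-down panels (tens of clones, tens to
hundreds of markers per chromosome, negative-SNP counts of a few hundred)
chosen to keep each stage's statistical behaviour in the regime of the real
panel — marker spacing of ~1–10 cR, LOD-10 linkage well above threshold
within chromosomes, the 1/Nneg floor below the 1% FDR band. Every stochastic
component takes an explicit seed; identical seeds reproduce byte-identical
artifacts, including through the command-line pipeline.

## Known limitations

- Retention is fitted as a single r per linkage group; retention gradients
  (centromere/selection effects) live only in the simulator, not the
  likelihood.
- The MCMC scores proposed orders with two-point-derived θ values, not a
  refit; with very noisy data this approximation flattens the posterior
  (which the robust-map extraction then correctly reports as uncertainty).
- The greedy robust-map extraction is a simplification of the unpublished
  inclusion-tree method; it can remove more markers than strictly necessary
  when several bins jump jointly.
- Two- and single-marker scaffolds cannot be oriented by the map (slope
  untestable); they rely on comparator synteny, as in the source pipeline.
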