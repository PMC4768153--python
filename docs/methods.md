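# Methods

This note documents the models and procedures `lousenet` implements, the
defaults and why, what the synthetic generator does and does not emulate,
and the numerical choices that matter.

## Networks and centrality

Scan records are split by season and reduced to dyadic counts. The
contact network is undirected: `weight(A,B)` is the number of minute-scans
of body contact — grooming included, since grooming is contact — between A
and B, pooling rows from both females' focal follows. The grooming
network is directed groomer → groomee (a `groom_given` row contributes
focal → partner, a `groom_received` row partner → focal); self-grooming
never forms an edge. All adult females present in the attribute table are
nodes, so females with no interactions appear as isolates with zero
centrality and enter the models with degree 0 rather than as missing.
Weights are raw scan counts, not rates: observation effort is balanced
across females by design, and count weights keep the rewiring null model
exact (weights travel with edges).

Centralities are the direct-exposure measures only — degree/strength,
in-degree/in-strength — because a louse needs body contact to transfer;
indirect measures (eigenvector, betweenness) answer a different question
and are out of scope.

### Modularity

Community structure per season is summarized by weighted Newman
modularity, maximized by leading-eigenvector bisection: split along the
sign pattern of the leading eigenvector of the generalized modularity
matrix, refine with a Kernighan–Lin single-node sweep (each node moved at
most once per pass, only sweeps that increase the split's contribution),
recurse, and stop when the leading eigenvalue is ≤ 1e−8 or a split fails
to increase Q. Singleton communities are allowed only if they increase Q.
The directed grooming network is symmetrized (reciprocal weights summed)
before detection because this modularity is defined for undirected
graphs; centralities remain directed. Q is computed on the weighted
adjacency by default (`binarize=True` is available; with the study's
near-complete, weight-heterogeneous networks the binarized Q is close to
degenerate). Against exhaustive enumeration of all partitions on 50
seeded random graphs of ≤ 8 nodes, the heuristic's worst shortfall was
0.019, so the test suite's 0.05 slack is comfortable.

## Dominance

David's scores use raw dyadic win proportions `P_ij`; dyads that never
interacted contribute zero to every component sum. A flag switches to the
chance-corrected index `Dij = P_ij − (P_ij − 0.5)/(n_ij + 1)` for
sensitivity analyses. Records are pooled across the study into one global
hierarchy — female macaque hierarchies are stable on this timescale — and
the resulting ordinal rank (1 = highest, ties broken by identifier order
and logged) is attached to every season row. Displacements and aggression
are weighted equally.

## Lice load

`load(id, season) = total egg picks attributed to id /
(grooming-received scans + self-grooming scans of id)`, in picks per
grooming minute-scan. Picks belong to the groomee (the focal on
`groom_received`/`self_groom` rows, the partner on `groom_given` rows).
Self-grooming picks are included in the numerator by default — they are
removals of the female's own eggs and the denominator includes
self-grooming effort — with a flag to exclude them. Rows with zero
qualifying scans are undefined (excluded from models with a warning), not
zero; picks without qualifying scans are a data inconsistency and raise.
Both totals and the ratio are emitted so alternative normalizations stay
auditable.

## Mixed models

One model per centrality measure (the measures are mutually correlated
and the frame has only ~80 rows). The response is
`z(log(load + c))` with `c` = half the smallest positive load in the
frame (configurable); the predictor is `z(√centrality)`; rank is
standardized ordinal. Standardization is global across the pooled frame
because season is a factor in the model. Controls: season (reference
winter), reproductive state (reference not_active), treatment (reference
untreated), random intercept per female.

Fitting is full ML, not REML, so every nested LRT in the procedure is
valid, and the reported estimates come from the same fits. For a single
random intercept the ML problem is one-dimensional: with
λ = σ²_id/σ²_res fixed, GLS estimates and both variances have closed
forms via the Woodbury identity, so the fitter only searches λ (bounded
Brent on [0, 200], boundary λ = 0 checked explicitly). This makes a fit
~3 ms, exactly deterministic, and independent of optimizer starting
points — properties the randomization test (thousands of refits per
dataset) and the byte-identical-rerun guarantee rely on. Agreement with
statsmodels `MixedLM` under ML is enforced in the test suite; on boundary
datasets the profiled fitter reliably attains the (equal or better)
optimum. When the true random-intercept variance is zero the fit reduces
to OLS exactly whenever the profiled optimum is on the boundary; a
chance positive variance estimate in a finite sample is correct ML
behavior, so the OLS-reduction tests assert boundary-case equality and
median agreement rather than per-draw agreement.

Pruning starts from
`centrality × season × reproductive_state` plus its three two-way
children and all main effects/controls, and eliminates backward by LRT,
highest order first: drop at p > 0.100, keep as "marginal" in
(0.050, 0.100], keep at ≤ 0.050. If the three-way survives, its children
are protected. Among two-ways, the currently least informative (largest
p) is dropped first and the remaining ones retested, so the trace records
an honest sequential procedure. Main effects and controls are never
pruned. The final model is tested against a null model containing only
controls not involved in any retained interaction, plus the random
effect; predictors are interpreted only when that LRT has p ≤ 0.05.
Asymptotic χ² references under ML are mildly anticonservative at n = 80
(measured: all four interactions are dropped on pure noise in ~44–59% of
replicates depending on condition, versus the naive 0.9⁴ ≈ 66%); this is
a property of the stated procedure, shared with any lme4-style ML/LRT
workflow at this sample size. Variance inflation factors are reported
with a warning above 5 and no automatic action.

## Network-randomization test

Each of R runs draws a rewiring intensity p ~ U(0,1), rewires every
seasonal network, recomputes the centrality, rebuilds the frame
(re-transforming and re-standardizing centrality, since rewiring changes
its distribution), refits the final fixed-effects specification, and
records the coefficient of the term of interest. The empirical p uses the
add-one rule with ties counted toward the tail (conservative); per-run
RNG streams are spawned from the master seed by run index so results are
independent of execution order. Runs that fail to converge or produce a
degenerate centrality column are dropped and counted; more than 5%
dropped is an error.

Two rewiring modes exist. *Endpoint rearrangement* (default for
inference) moves one randomly chosen endpoint of each selected edge to a
uniformly random node, rejecting self-loops and duplicates — the natural
null for "who holds many connections". *Degree-preserving double-edge
swaps* conserve every node's degree by construction and are used for the
structural invariants and for strength-based sensitivity analyses; they
cannot serve as the null for a degree-based test, because degree
centrality is invariant under them and the test would be vacuous. The
choice between the two is the one place where the method's common verbal
description ("rearrange edges, keeping the degree distribution") is
internally inconsistent; the package resolves it in favor of a null that
actually randomizes the tested quantity, and exposes both modes.

The test is conservative by construction: β_rand is computed on networks
drawn from a *perturbation* family around the observed network, whose
spread exceeds the sampling variability of β_obs (measured ~1.3× under
the generator null). Calibration measured on 100 synthetic null datasets
at R = 200 (lower tail): rejection rate 0.01 at α = 0.05, KS uniformity
p = 0.022. Power with the default seeded effect (−0.5 on the generator's
winter and summer degree coefficients): winter and summer slopes negative
in 100% of 100 replicates, permutation p ≤ 0.05 in 56%. R defaults to
2000 for analysis runs; tests and the acceptance script use R = 200 and
60–100 replicate datasets, which keeps the full suite within minutes on
one core at Monte-Carlo error small relative to the frozen bands.

## Synthetic generator

Per focal and season, a fixed budget of recorded minute-scans (default
96, roughly the social + self-grooming fraction of a ~260-minute seasonal
follow) is allocated multinomially over plain contact with each partner,
grooming with each partner, and self-grooming, with dyadic weights
`gregariousness_i × gregariousness_j × affinity_ij` (gamma-distributed;
affinity shape 0.4 makes them heavy-tailed so degree varies), a seasonal
sociality factor (reduced in summer/fall), and grooming direction biased
up the hierarchy (0.6 vs 0.4). Reproductive state follows the study
design: 10 females in oestrus in winter, 7 mothers (drawn from the
oestrous set) active in spring/summer/fall; 11 females treated
throughout. Agonistic outcomes follow a transitive latent order with 10%
upsets and 150 decided interactions per season (~3 per dyad over the
study — realistic for a provisioned macaque group and enough for David's
scores to track the latent order at Spearman ρ ≥ 0.96).

Latent lice intensity per female × season is
`λ = exp(intercept + season offset + β_deg[season]·z(degree) +
β_repro·active + β_treat·treated + noise)`, with z(degree) the
within-season z-score of realized contact degree, so seeded coefficients
are approximately on the scale the models estimate. Egg picks per
grooming row are negative-binomial with mean λ (gamma–Poisson, dispersion
1.0 by default, 1.5 in the study defaults); the intercept `log 0.7` and
season offsets (summer and fall elevated) put the median load near 0.9
picks per grooming minute-scan with seasonal means mirroring a
late-summer peak. No effect sizes exist on the count scale in the source
literature; all coefficients are surfaced in `SynthConfig`, not
hard-coded.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: males, juveniles and their network layers;
within-season temporal autocorrelation and between-season carry-over of
lice; observation error in partner identification; kin structure in
affinities; density-dependent louse demography. The generator's exact
within-season z(degree) linkage is also cleaner than any plausible field
mechanism; the mismatch between it and the models' global z(√degree)
transform is deliberate realism in the *analysis* direction (the analysis
never sees the generator's scale), and is why the unseeded three-way
interaction survives pruning more often (26%) than its nominal 10%.

## Degenerate inputs and tie-breaks

Constant response/centrality/rank columns raise naming the column; an
all-zero lice-load frame raises. normDS ties break by identifier order
with a logged warning. Zero-weight networks have Q = 0 and one community.
Rewiring proposals that would create self-loops or duplicates are redrawn
up to 10 times, then skipped, so graphs with no admissible move (e.g. a
triangle under swaps) pass through unchanged. LRTs clip χ² at 0; a
reduced model can never report a higher ML log-likelihood than its
nesting model beyond 1e−6 (asserted).
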