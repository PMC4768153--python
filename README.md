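# lousenet

Seasonal social-network analysis of ectoparasite (louse) load in a primate
group.

Social grooming cuts both ways for a directly transmitted ectoparasite:
body contact gives lice a bridge between hosts, while grooming removes
louse eggs. `lousenet` implements the full observational analysis chain
used to weigh these two forces against each other in a group of adult
female Japanese macaques, where louse burden can be scored non-invasively
from the conspicuous egg-picking gesture groomers perform. It is aimed at
behavioural ecologists and disease ecologists who have focal-animal scan
data and want the network / dominance / mixed-model / randomization chain
as tested, reusable code.

## The analysis

From minute-scan focal records split into four seasons (winter = mating
season, spring, summer = birth season, fall), the pipeline computes:

1. **Seasonal weighted networks** — an undirected *contact* network
   (edge weight = dyadic count of body-contact scans, grooming included)
   and a directed *grooming-received* network (groomer → groomee).
   Centralities are degree *k* and strength *s* (contact) and in-degree /
   in-strength (grooming received); community structure is summarized by
   modularity *Q*, maximized by Newman's leading-eigenvector bisection of
   the weighted modularity matrix `B = A − k kᵀ/2m`.
2. **Dominance** — normalized David's scores from decided agonistic
   interactions, `DS = w + w2 − l − l2`, `normDS = (DS + N(N−1)/2)/N`, and
   ordinal ranks (1 = highest).
3. **Lice load** — per female × season,
   `load = egg picks / (grooming-received + self-grooming minute-scans)`,
   in picks per grooming minute-scan, picks attributed to the groomee.
4. **Mixed models** — Gaussian random-intercept models (full ML) of
   z-standardized `log(load + c)` on z-standardized `√centrality`, season,
   reproductive state, standardized rank and anthelminthic treatment, with
   a centrality × season × reproductive-state interaction pruned backward
   by likelihood-ratio tests (drop at p > 0.100, marginal keep in
   (0.050, 0.100]), and a final-vs-control-only null-model LRT.
5. **Network-randomization test** — the observed coefficient β_obs is
   located in the distribution of β_rand over R model refits on rewired
   networks (rewiring intensity ~ U(0,1) per run);
   `p = (1 + #{β_rand ≤ β_obs}) / (R + 1)` for the lower tail.

Because field datasets of this kind are rarely deposited, the package
ships a first-class synthetic generator (`lousenet.synth`) that emulates
the study design — 20 females, per-female scan budgets, heavy-tailed
dyadic affinities, up-hierarchy grooming, a stable linear hierarchy, and a
configurable season-dependent effect of degree on latent lice intensity —
so every stage, and the whole inference chain, is testable against known
ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole chain on the default
synthetic study (seeded degree coefficients winter = summer = −0.5,
spring = fall = 0):

```
$ python analysis/01_simulate.py
$ python analysis/04_fit_models.py
degree: interactions kept: centrality:season
  season-specific centrality slopes: {'winter': -0.99, 'spring': 0.2, 'summer': -0.95, 'fall': 0.25}
  final vs null LRT: chi2=74.9 df=7 p=0.0000
strength: interactions kept: none
  season-specific centrality slopes: {'winter': -0.02, ...}
  final vs null LRT: chi2=0.0 df=1 p=0.8854
$ python analysis/05_permutation.py 300 11
centrality: beta_obs=-0.989 p(beta_obs < beta_rand)=0.047 (significant at the 95% criterion, R=300)
```

Read: the degree model recovers the seeded pattern — females with more
partners carry fewer lice in winter and summer only (negative winter and
summer slopes, near-zero spring/fall), the interaction survives pruning,
and the winter slope is more negative than expected from randomized
networks (p = 0.047). The strength model, correctly, finds nothing: the
seeded effect acts through number of partners, not total contact time.

The same chain is available as a CLI (`lousenet simulate`, `lousenet run
--measure degree --reps 2000`) or via `lousenet.run_pipeline`.

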