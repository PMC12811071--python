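# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `herbnet`. It describes what the code
computes and why the defaults are what they are; every number quoted here is
produced by the test suite or `scripts/acceptance.py`, not asserted from
elsewhere.

## The phase model

A bipartite network of plant individuals and herbivore species is in one of
two structural phases: fragmented into many small components, or dominated by
a giant component. Under the configuration-model assumption (degree sequence
fixed, wiring otherwise random), the transition is governed by the sign of

    C = Σ_{m=1}^{D_plants} Σ_{n=1}^{D_animals} m n (m n − m − n) p_m p_n ,

where `p_m`, `p_n` are the relative frequencies of plant/herbivore binary
degrees and `D_*` the largest observed degree on each side. `C > 0` predicts
a giant component. Degree is *binary* — the number of distinct partners —
so C is invariant to the event counts; counts enter only the interaction
probabilities `p_i` and the bootstrap. Nodes with zero realized interactions
are excluded from the degree distributions, the component census and the
largest-component denominator (the sums above start at degree 1, and
bootstrap replicas contain only sampled interactions); `include_isolated=True`
retains manifest-declared uninfested plants as a sensitivity check on the
denominators, without entering C.

The criterion is validated in the acceptance suite by simulation: bipartite
configuration-model graphs built from degree sequences with C ≫ 0 average a
largest-component fraction above 0.8, and sequences with C < 0 stay below
0.5 (200 graphs each, graphs generated by networkx independently of the C
computation).

## Bootstrap

Confidence intervals come from resampling interaction *events* with
replacement, with probability proportional to the recorded counts — a
multinomial redraw over cells with `n_events` draws (default: the source
network's own total, so totals are conserved exactly). Each replica may lose
nodes whose cells were never drawn; metrics see only realized nodes. A
metric undefined on a degenerate replica is recorded as missing and counted,
never silently dropped. One master seed spawns a `SeedSequence` substream
per replica, so replica r is identical whether 10 or 10,000 replicas are
requested. Percentile (2.5/97.5) intervals only; no BCa or studentized
variants.

## Katz total effects and the indirect contribution

The block adjacency `A = [[0, B], [Bᵀ, 0]]` is built from the binary
incidence matrix, plants first, lexicographic within set. Walk counts of
length ℓ (walks may revisit nodes and edges) are `A^ℓ` by repeated integer
matrix multiplication. Discounting length geometrically gives the Katz
series, whose closed form is the total-effects matrix `T = (I − αA)⁻¹`,
computed by dense linear solve (networks here have ≲ 100 nodes). Convergence
requires `α < 1/λ` with λ the spectral radius of A; the default decay is

    α = 1/(λ + 0.01),

the smallest admissible decay up to the 0.01 shift — i.e. the slowest decay
for which the series still converges, weighting long indirect pathways as
heavily as possible. An alternative rule `fraction_of_inverse`
(`α = 0.99/λ`) is exposed for sensitivity analyses. T includes the ℓ = 0
identity term; the indirect contribution

    U = Σ_{i≠j} (1 − a_ij) t_ij / Σ_{i≠k} t_ik

excludes the diagonal from both sums, so this choice does not affect U. U is
computed on the full (possibly disconnected) matrix; cross-component entries
of T are exactly zero, so disconnection only enters through the denominator's
node set. The solve is cross-checked in the tests against an independent
term-by-term truncated power series; the truncation length is chosen with
the decay kept safely inside the convergence region, since near the
boundary (`αλ → 1`) a fixed-length series converges arbitrarily slowly.

## Phytochemical diversity

Compositional PD is the Shannon entropy (nats, by default) of a leaf's
compound-level intensity profile; structural PD the entropy of its
substructure-level profile. Intensities are normalized to proportions; zero
features contribute nothing, so H is scale-invariant and bounded by
ln(number of positive features). Leaf entropies are aggregated to the plant
by the mean; the aggregation statistic is configurable because no single
convention exists — results for strongly skewed leaf profiles can depend on
it. No spectral preprocessing (peak picking, alignment, binning) is done
here; the input is a processed intensity table.

## Piecewise path model

The default DAG: season → compositional PD; season, compositional PD and
structural PD → `p_i`; compositional and structural PD → herbivory. Each
endogenous variable gets its own regression on its parents — OLS for
Gaussian responses; for `p_i`, a binomial GLM with an events/trials response
(successes = the plant's event count, trials = its season's grand total),
since `p_i` is a proportion of counts. Season is coded 0/1 with dry = 1.

Standardized coefficients: `β_std = b·sd(x)/sd(y)` for Gaussian responses;
binomial coefficients are standardized on the latent logit scale with
`sd(y) = sqrt(var(η) + π²/3)`. Indirect effects are products of standardized
coefficients along a directed path.

Goodness of fit uses the d-separation basis set: every non-adjacent
unordered pair with at least one endogenous member, conditioned on the union
of both members' parents. The tested regression's response is the pair
member later in topological order, except that a Gaussian response is
preferred over a binomial one when neither member is an ancestor of the
other (numerically better behaved, and the Wald test of the added partner is
the same claim). Claim p-values aggregate into Fisher's `C = −2 Σ ln p_k`,
χ² with `2k` df. For the default DAG this construction yields three claims
(compositional ⊥ structural PD | season; herbivory ⊥ season | PD;
herbivory ⊥ p_i | season, PD), hence df = 6. Basis-set conventions differ
between implementations (some omit additional claim types and produce fewer
df for the same DAG), so Fisher's C values are only comparable within one
convention; the construction used here is stated explicitly. Its calibration
is what matters and is tested directly: under data simulated from the true
model the test rejects at ≈ 4–5% at nominal α = 0.05 (500 simulations in
the acceptance suite).

Pseudo-R² for binomial responses is Nagelkerke by default (McFadden
available); the choice is a convention, reported alongside the value.

## The synthetic generator

The generator reproduces the study conditions the analysis assumes, per
season:

| quantity | default | rationale |
|---|---|---|
| plants per season | 62 | field sample size (different individuals per season) |
| herbivore species | 18 | field species pool |
| rainy / dry event totals | 29 / 244 | observed seasonal abundance contrast |
| herbivore skew (Dirichlet conc.) | 50 (rainy), 0.12 (dry) | even rainy assemblage vs. two dominant dry species (~70% and ~20% of events) |
| within-plant clustering | 0.1 | broods: events on one plant are usually one species |
| season → compositional PD | 1.2 sd | strong, detectable seasonal chemistry shift |
| compositional PD → attractiveness | +0.6 | more diverse chemistry, more herbivore species attracted |
| structural PD → attractiveness | −0.5 | structurally diverse defenses deter |
| season → attractiveness | −0.4 | see identifiability note below |
| structural PD → herbivory | −0.6 sd | defense lowers leaf damage |
| residual sd (per response) | 1.0 | moderate noise; herbivory on a 0–100% scale (mean 30, scale 10) |

Events are allocated by a single multinomial over cells with probability
`softmax(attractiveness)_plant × preference_plant,herbivore`, which conserves
the season total exactly. Preferences are plant-level Dirichlet draws
centred on the season's species abundances (`E[pref] = abundance`); the
small concentration makes the events on one plant cluster on few species.
Without this clustering the rainy network's empirical C sits at the critical
point rather than clearly below it, because independent repeat events on a
plant land on different species and inflate plant binary degrees — an
artifact gregarious, clutch-laying caterpillars do not show.

**Identifiability note.** An additive season term inside the softmax cancels
within a season (each season's `p_i` sums to 1 by construction), so the
fitted season → `p_i` path does not estimate that term. What it estimates is
the renormalization induced by the season shift of compositional PD: with a
mean shift δ and attractiveness weight b, the within-season normalizer grows
by ≈ e^{bδ}, so the fitted season coefficient is ≈ −bδ < 0 — the dry season
*lowers* a typical plant's share because a few chemically attractive plants
absorb the extra events. The generator's season → attractiveness default is
set negative to match the sign its fitted counterpart carries.

What the generator does **not** emulate: spatial autocorrelation among
plants, within-season temporal dynamics, herbivory-induced chemical
responses, observation error in PD, and any correlation between the two PD
dimensions (they are generated independently). Passing tests therefore show
that the pipeline recovers the structure it assumes at field-realistic
sample sizes — not that field data satisfy those assumptions.

## Problem sizes and determinism

The acceptance script uses 2,000 bootstrap replicas per season (and per
sensitivity grid point at 29/136/244 sampled events); distributional test
properties use 100 generator seeds (phase contrast, path recovery) and 500
simulated datasets (d-separation calibration); the Katz oracle uses 50
random bipartite graphs of up to 40 nodes. These sizes give stable means
(bootstrap SE of the reported means is far below the effects of interest)
while keeping a full run fast. All randomness flows from explicit seeds:
the generator through `SyntheticConfig.seed`, the bootstrap through
per-replica `SeedSequence` substreams, the pipeline through one master seed,
so reports are byte-identical across reruns.

## Numerical choices and degenerate inputs

* Labels are sorted lexicographically on ingest; matrix indices are
  reproducible across runs and dialects.
* All-zero networks, all-zero intensity profiles, zero event totals, and
  `n_events ≤ 0` are validation errors, not silent empties.
* Component ties report the tied maximum size; `frac_largest = 1` implies a
  single component.
* `λ = 0` (empty adjacency) gives `T = I` under the default α rule; the
  `fraction_of_inverse` rule is undefined there and says so.
* Walk counts use int64; counts overflow for long walks on dense graphs
  (λ^ℓ growth), so pathway lengths beyond ~15 on these networks should use
  the Katz-weighted T instead.
* Claim p-values are floored at 1e−300 before the log in Fisher's C.

## Known limitations

* Fisher's C values are comparable only within a fixed basis-set convention
  (see above); tools using a different basis set will report different df
  for the same DAG.
* The binomial events/trials formulation treats a season's plants as sharing
  one trial denominator; the mild negative dependence between plants' counts
  (the multinomial total is fixed) is ignored by the GLM.
* U mixes components only through its denominator when a network is
  disconnected; per-component U is not reported.
* The bootstrap resamples events independently; it does not model
  within-brood correlation, so replica variance for clustered data is
  conservative relative to a cluster bootstrap.
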