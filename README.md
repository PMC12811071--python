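# herbnet

Critical structural transitions in individual-based plant–herbivore networks.

`herbnet` is for ecologists studying how the architecture of a bipartite
network of plant *individuals* × herbivore *species* shifts between a
**disconnected phase** (many small components) and a **connected phase**
dominated by a giant component, and what that shift does to the potential for
indirect (cascading) effects. The motivating system is a tropical shrub whose
caterpillar assemblage changes drastically between the rainy and dry seasons,
with the plants' phytochemical diversity (PD) as the key individual trait.

## What it computes

**Phase diagnostics.** For a bipartite network with binary degree
distributions `p_m` (plants) and `p_n` (herbivores), the connectivity
parameter

```
C = Σ_m Σ_n  m n (m n − m − n) p_m p_n
```

is positive exactly when a configuration-model network with those degrees
contains a giant component. `herbnet` reports C alongside the component count
and the fraction of nodes in the largest component, with confidence intervals
from a frequency-proportional bootstrap (interaction events resampled with
replacement, with probability proportional to recorded counts).

**Indirect pathways.** From the block adjacency `A = [[0, B], [Bᵀ, 0]]` it
computes the Katz total-effects matrix `T = (I − αA)⁻¹` with decay
`α = 1/(λ + 0.01)` (λ = spectral radius), walk counts `A^ℓ` per length, and
the indirect-pathway contribution

```
U = Σ_{i≠j} (1 − a_ij) t_ij / Σ_{i≠j} t_ij ,
```

the share of total pairwise effect mass carried by non-adjacent pairs.

**Drivers.** Per-plant interaction probabilities `p_i = Σ_j w_ij / Σ_ik w_ik`
are linked to seasonality and to compositional/structural PD (Shannon
entropies of processed spectral profiles) through a piecewise path model:
one regression per endogenous variable (binomial events/trials GLM for
`p_i`, Gaussian otherwise), standardized coefficients, indirect-effect
products, and a d-separation goodness-of-fit test aggregated into Fisher's
`C = −2 Σ ln p` (χ², df = 2 × number of claims).

**Synthetic data.** A paired-season generator reproduces the study
conditions (62 plants and 18 herbivore species per season; 29 rainy events
spread evenly vs. 244 dry events concentrated on two dominant species;
covariates tied to interactions through known path coefficients), so every
stage is testable end-to-end without field data.

## Worked example

```python
import herbnet as hn

study = hn.generate_paired_study(hn.SyntheticConfig(seed=1))
result = hn.run_study(study.networks, study.covariates,
                      hn.StudyConfig(replicas=1000, seed=1))
```

Summarizing `result.report` prints:

```
rainy: components 8.60 ± 1.67   frac_largest 0.30 ± 0.09   C -1.10 ± 0.31   U 0.59 ± 0.08
  dry: components 2.99 ± 0.73   frac_largest 0.93 ± 0.03   C 306.07 ± 64.15  U 0.80 ± 0.01
fold change of mean U (dry/rainy): 1.34
Fisher's C = 4.82, df = 6, p = 0.57, pseudo-R2(p_i) = 0.66
            season -> compositional_pd beta_std = +0.56  (p = 9.72e-12)
  compositional_pd -> p_i              beta_std = +0.34  (p = 1.15e-19)
            season -> p_i              beta_std = -0.17  (p = 0.00195)
     structural_pd -> p_i              beta_std = -0.25  (p = 5.96e-15)
  compositional_pd -> herbivory        beta_std = +0.05  (p = 0.542)
     structural_pd -> herbivory        beta_std = -0.42  (p = 9.88e-07)
```

Read: in the rainy season the network is fragmented (8.6 components, largest
holding 30% of nodes, C < 0 — subcritical), while the dry season network is a
giant component (93% of nodes, C ≫ 0 — supercritical). The indirect-pathway
share U jumps 1.34-fold across the transition. The path model attributes the
shift in interaction probabilities to season and to the two PD dimensions
acting in opposite directions (compositional +, structural −), and the
d-separation test does not reject the model (p = 0.57).

The same pipeline runs from the shell:

```bash
herbnet simulate --out-dir data/ --seed 1
herbnet phase --net data/interactions.csv
herbnet run --interactions data/interactions.csv \
            --covariates data/covariates.csv --out-dir out/
```

Field data in the same CSV formats (long interaction table
`plant_id,herbivore_id,count,season`; covariates
`plant_id,season,compositional_pd,structural_pd,herbivory`) drop in directly.

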