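# genomealg

Maximum-likelihood rearrangement distances for circular genomes, computed
inside a symmetry-reduced **genome algebra**.

A circular genome with `N` unoriented regions and no distinguished position
is the same physical object in any of its `2N` reference frames, so it is
modelled not as a single permutation but as a *permutation cloud*: the
normalized sum `z·σ` over the dihedral group (or any symmetry subgroup
`Z ⊆ S_N`). Clouds form the genome algebra `A = z·C[S_N]` of dimension
`K = N!/|Z|`. A rearrangement model — a set of allowed rearrangement types
with weights, closed under the genome's symmetry (M1) and optionally under
inversion (M2) — induces a model element whose reduced irreducible
representations are small symmetric matrices (`k_p × k_p` instead of
`D_p × D_p`). Their spectra give closed-form path probabilities

```
alpha_k(σ) = (|Z|/N!) Σ_p D_p Σ_i λ_{p,i}^k · tr(ρ_p^A(zσ⁻¹) E_{p,i})
```

and, with Poisson(1) event times, the likelihood curve
`L(T|σ) = e^{-T} (|Z|/N!) Σ D_p tr(·) e^{λT}` whose maximiser is the MLE
of evolutionary time. The curve may be monotone up to its stationary value
`1/K`; in that case no finite MLE exists and the result is flagged.

Everything is cross-checked against a brute-force Markov chain on the `K`
genome clouds (exact rational transition matrix, truncated Poisson sums)
and against the unreduced group-algebra route.

## Layout

| module | contents |
| --- | --- |
| `genomealg.perm` | permutations, subgroups (dihedral/reflection/rotation/custom), coset and double-coset machinery, exact sparse group-algebra elements |
| `genomealg.sn_irreps` | partitions, hook-length dimensions, Young's orthogonal form, characters |
| `genomealg.genome_algebra` | symmetry element `z`, projections `ρ_p(z)`, reduced irreps `(Q_p, k_p)`, regular character of `A`, double-coset counts via Burnside |
| `genomealg.rearrangement_model` | model building (M1/M2 closure, weight splitting, duplicate-cloud-action detection), model elements, reduced model matrices |
| `genomealg.likelihood_mle` | spectral decomposition, `alpha_k`, likelihood curves, MLE search, full-group cross-check route |
| `genomealg.markov_oracle` | exact `K×K` cloud Markov matrix, matrix-power path probabilities, Poisson-series likelihood, `N!×N!` permutation chain |
| `genomealg.config_io`, `genomealg.fixtures`, `genomealg.cli` | JSON model configs, deterministic fixture models, command-line interface |

## CLI

Model config (JSON):

```json
{
  "N": 6,
  "symmetry": "dihedral",
  "reversible": true,
  "rearrangements": [
    {"perm": "(1 2)", "weight": "2/3"},
    {"perm": "(1 3)", "weight": "1/3"}
  ]
}
```

Weights are per rearrangement *type*; each type is expanded into its
symmetry orbit with the weight split uniformly over the orbit's distinct
permutations, then normalized. Two types with identical cloud actions
(e.g. 2- and 3-region inversions at N=5) are rejected with an error.

```sh
genomealg dims --n 6 --symmetry dihedral          # partition, D_p, k_p table
genomealg validate-model --model model.json       # echo the expanded model
genomealg pathprobs --model model.json --genome "(1 2)" --kmax 8
genomealg likelihood-curve --model model.json --genome "2 1 3 4 5 6" -o curve.tsv
genomealg mle --model model.json --genome "(2 4 6)"   # JSON record; mle_time is null when no finite MLE exists
```

Genomes are accepted in one-line (`"2 1 3 4 5 6"`) or cycle (`"(1 2)"`)
notation.

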