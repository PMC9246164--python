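# netmsa

Causal contribution mapping of recurrent networks by perturbation.

`netmsa` quantifies what each node and connection of a recurrent
NEAT-style network contributes to its task performance by lesioning the
network in a principled way:

- **SPA** — single-element perturbation analysis: lesion one element at a
  time and measure the performance change.
- **MSA** — multi-perturbation Shapley-value analysis: treat elements as
  players in a coalition game whose worth is lesioned-network performance,
  and estimate each element's Shapley value γ with a permutation-sampling
  estimator (exact enumeration for small games).
- **PCIA** — pairwise causal interaction analysis: for each pair (i, j),
  compare the joint contribution γ₍ᵢⱼ₎ of the fused pair with the
  conditioned contributions γ(i, j̄) and γ(j, ī), each computed with the
  other member permanently lesioned. The interaction term
  I = γ₍ᵢⱼ₎ − γ(i, j̄) − γ(j, ī) measures net synergy (> 0) or redundancy
  (< 0). A **paradoxical-lesion (Sprague) effect** from i to j is declared
  when γ(i, j̄) < 0 and I + γ(i, j̄) > 0: element i actively hurts once j is
  gone, although the pair as a whole is beneficial.
- **FC/IFC** — functional connectivity (Pearson correlations of node time
  series) and the impact of each lesion on it (absolute element-wise sum of
  the FC difference matrix), to show that dynamical impact and causal
  contribution dissociate.
- **stats** — mean-shifted bootstrap hypothesis tests, percentile bootstrap
  confidence intervals, Bonferroni correction and Mann–Whitney U.

Why single lesions are not enough: a network can hide both redundancy (two
elements backing each other up, so neither single lesion shows a deficit)
and paradoxical interactions (a second lesion *restoring* a deficit the
first one caused). Multi-perturbation analysis reveals both.

## The bundled fixture

`make_motif_genome()` (also shipped as `src/netmsa/data/motif_genome.json`)
is a small synthetic ground-truth network built around an inhibitory
self-loop motif. Node 0 pools a positive drive from input −4 against its
own negative self-loop (0→0); the task rewards choosing action 4 at every
timestep. The fixture is calibrated so that, on the default task:

- the intact network scores ≥ 0.8 of the maximum;
- lesioning (0→0) alone collapses performance to ≤ 0.3 of maximum;
- lesioning (0→0) **and** (−4→0) together restores ≥ 0.8 of maximum — the
  paradoxical lesion effect;
- lesioning (−4→0) alone, or all of node 0's connections, changes
  performance by less than 5%.

So SPA flags only (0→0), MSA additionally assigns a *negative* γ to
(−4→0), and PCIA identifies {(0→0), (−4→0)} as the maximal-interaction pair
with a single Sprague edge whose stem is (−4→0). See `docs/methods.md` for
how the fixture works internally.

## Worked example

```python
from netmsa import (TaskSpec, make_motif_genome, lesion_game,
                    sampled_shapley, spa)
from netmsa.pcia import interaction_matrix, threshold_pairs, detect_sprague

genome = make_motif_genome()
task = TaskSpec(seed=7)                   # 200 steps, reward 10/hit, max 2000
game = lesion_game(genome, task, "connections", plays_per_eval=2, seed=13)

res = spa(game, n_trials=64)
res.effect[(0, 0)]        # ~ -1460  (self-loop lesion is catastrophic)
res.effect[(-4, 0)]       # ~ +4     (drive lesion alone is harmless)

table = sampled_shapley(game, n_permutations=200, seed=1)
table.gamma[(0, 0)]       # ~ +725   (largest gamma, rank 1)
table.gamma[(-4, 0)]      # ~ -624   (negative: net harmful given the rest)

m = interaction_matrix(game, n_permutations=50, seed=0)
edges = detect_sprague(threshold_pairs(m, k_sd=2.0), m)
# [SpragueEdge(stem=(-4, 0), head=(0, 0), interaction=~+1180,
#              gamma_conditioned=~-1111)]
```

The same pipeline is exposed as a CLI (`netmsa spa|msa|pcia|fc|fixtures`);
every command writes its result tables plus a `manifest.json` that is
sufficient to re-run it bit-identically. Canonical oracle games (additive,
unanimity, glove, OR) can be fed to the Shapley/PCIA commands through
`--game-file` without any network. Run `netmsa --help` for the flags;
defaults follow the analysis protocol throughout (1000 MSA permutations,
100 PCIA permutations, 512 trials of 16 plays, 10,000 bootstrap resamples,
α = 0.05, ±2 SD interaction threshold).

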