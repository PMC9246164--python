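# Methods

## Network model

A network is described genetically: node genes carry a role
(input/hidden/output), a bias, a response multiplier and the names of an
activation and an aggregation function; connection genes are weighted,
directed, and carry an `enabled` flag (disabled connections are pseudogenes
that pass zero and are removed by `prune_disabled`). The update is
synchronous with a one-step delay: at time t every non-input node reads the
t−1 activations of its non-input sources and the time-t values of its input
sources, so self-loops are well defined and update order is irrelevant. A
node whose surviving input set is empty aggregates to 0 (its output is then
`act(bias)`).

Action selection is winner-take-all over the output nodes, ties broken to
the lowest output id. An episode's score is the number of timesteps on
which the chosen action equals the task's target action, times a per-hit
reward; only orderings and ratios of scores are meaningful.

A lesion is a severed connection; a node lesion severs all of the node's
incoming and outgoing enabled connections. Masks are idempotent and
validated against the genome.

## Games and estimators

`lesion_game` turns a genome plus task into a coalition game: elements are
node ids or enabled-connection keys, and the worth v(S) of a coalition S is
the mean score of the network with every element *outside* S lesioned. The
replicate noise stream is derived deterministically from
(seed, lesion-mask key, trial index), so a coalition's worth is identical
whenever it is revisited, and coalition values are memoised.

One convention matters for the efficiency axiom: a fully lesioned network
still emits actions (all-zero activations tie-break to the lowest output
id), so v(∅) is generally > 0. All efficiency statements therefore target
Σγ = v(N) − v(∅).

`exact_shapley` evaluates the subset-weighted sum
Σ_S |S|!(n−|S|−1)!/n! · Δᵢ(S) over all 2ⁿ coalitions (n ≤ 12 by default);
`sampled_shapley` draws uniform orderings with replacement and walks each
ordering from the empty coalition upward, so an ordering costs at most n+1
coalition evaluations and shared prefixes are never re-evaluated. PCIA
builds three derived games on top of the same base game (fused compound
element; each element with the other permanently lesioned) so all three γ
estimates share one memoisation pool.

Interactions are thresholded at ±2 SD over the unique unordered
off-diagonal entries of the interaction matrix (signed values, population
SD); both ordered directions of each surviving pair are tested for the
Sprague condition γ(i, j̄) < 0 ∧ I + γ(i, j̄) > 0.

## The motif fixture

The fixture's definition is behavioral, not structural: its weights are
fixed constants chosen once to satisfy the documented contract (intact
≥ 0.8·max; loop cut ≤ 0.3·max; loop+drive cut ≥ 0.8·max; drive cut and
full node-0 lesion within 5% of intact) and the PCIA recovery property
(maximal-|I| pair {(0→0), (−4→0)}, single Sprague edge stem (−4→0)). They
are recorded in the genome metadata and frozen by regression tests.

Internally the fixture is a competition between two actions driven by
anticorrelated inputs. Node 4, the rewarded action, follows input −1 (the
stimulus s(t), a decaying oscillation); node 2 is a "pressure" action whose
moderate bias plus a small dither from input −2 lets it win only during
deep stimulus troughs. Node 0 pools the drive from input −4 (≈ 1 − s(t))
against its negative self-loop, so the intact node 0 oscillates in a mid
band. Four hidden detector channels read node 0 and steer the pressure:

- two redundant high-activity detectors (nodes 10, 11) suppress node 2
  while node 0 peaks — exactly the window in which node 4 is weakest;
- a low-band detector (node 6) behind a purely feedforward relay chain
  (8 → 9 → gate 7) suppresses node 2 when node 0 sits in the low flat band
  it occupies once the drive is severed, or at zero when node 0 is lesioned
  outright — this is why those lesions are harmless;
- a runaway detector (node 12) excites node 2 once the severed self-loop
  lets the drive push node 0 beyond its intact peaks — this is the
  catastrophic loop-cut deficit.

Severing both key connections returns node 0 to the low band, the band
channel quiets the pressure, and performance is restored: the paradoxical
lesion effect. The channel depths (2-element supports for the redundant
high detectors, a 5-element support for the band chain) were chosen from
the ordering combinatorics of the permutation space so that the Sprague
inequalities hold with real margins under the sampled estimators, not just
at a single point.

Two structural choices are deliberate and load-bearing. First, node 0 uses `sum` aggregation: with inputs in
[0, 1] and a sigmoid state, every incoming term except the self-loop term
is ≥ 0 while the self-loop term is ≤ 0, so a `max` aggregate could never be
lowered by the negative self-loop — the self-loop would be an exact null
player and the paradoxical effect would be unsatisfiable in this small
fixture (`max` remains available as an aggregation for general genomes).
Second, only the inert outputs (1, 3, 5) carry the strong negative bias;
the functional outputs 0, 2 and 4 carry the biases the contract requires.

## Statistics

Significance uses the mean-shifted bootstrap: the sample is translated so
its mean equals the null mean, resampled with replacement n_boot times, and
the p-value is the add-one-corrected fraction of bootstrap means at least
as extreme as the observed mean (two-sided by default; floor 1/(n_boot+1)).
Shapley contributions are tested against a null mean of 0, SPA lesioned
distributions against the intact mean; families of tests share a
Bonferroni-corrected α. Confidence intervals are percentile bootstrap
intervals of the mean. Rank-sum comparisons delegate to the tie-corrected
Mann–Whitney U; FC uses Pearson correlation. Both are standard procedures
delegated to scipy.

## Limitations

- The surrogate task scores winner-take-all choices; absolute scores carry
  no meaning outside this package.
- PCIA is pairwise; higher-order interactions are out of scope.
- The sampled estimators inherit Monte-Carlo error; all reported seeds and
  budgets are surfaced in the CLI manifest so runs are reproducible.
- FC is computed from a single episode pair (intact vs lesioned under the
  identical stimulus); windowed or trial-averaged FC is not implemented.
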