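# Methods

## Model

`lhdnet` treats a protein–protein interaction network as a weighted
undirected graph and candidate-gene discovery as heat diffusion. With
adjacency `A`, degree diagonal `D` and Laplacian `L = D − A`, the heat
vector evolves as `H(t) = H(0) e^(−Lt)`; `H(0)` places `1/|S|` on each seed
(a validated driver gene of one omics level) and 0 elsewhere. The semigroup
`e^(−Lt)` is doubly stochastic in the limit sense relevant here: it
conserves total heat, maps nonnegative vectors to nonnegative vectors, never
moves mass between connected components, and converges within each
component to the uniform distribution as `t → ∞`.

The underlying assumption is guilt-by-association: genes topologically
close (through high-confidence interactions) to many validated drivers
accumulate heat faster than distant ones. The three-stage screen then
controls the known failure modes of raw diffusion: hubs that are warm under
*any* seeding (permutation test), candidates with no strong direct link to a
validated driver (association test), and candidates functionally unrelated
to the drivers (function test).

## Edge weights

STRING-style confidence scores are integers in [1, 999]. Three adjacency
modes are exposed because the generic diffusion equation does not fix one:

- `scaled` (default): `A_ij = confidence/1000`. Weights are O(1), so
  dimensionless diffusion times of order 1–10 mix local neighborhoods;
- `raw`: the integer score (timescales shrink by ~1000×);
- `binary`: 1 per edge, ignoring confidence.

Duplicate directed records in a links file collapse to one undirected edge
keeping the maximum score; edges below `min_confidence` are dropped but
their endpoints are retained as isolated nodes, so vector indexing depends
only on the input file, not on the filter. Node order is lexicographic,
making every vector reproducible across runs.

## Computing the heat-kernel action

For networks under 500 nodes the Laplacian is eigendecomposed once
(`scipy.linalg.eigh`) and `e^(−Lt) h` is applied in the eigenbasis; the
decomposition is cached on the operator, which makes the 500 permutation
replicates essentially free (two dense matrix–vector products each).
Eigenvalues are clipped at 0 before exponentiation to suppress negative
round-off eigenvalues. For larger networks the action is computed by
`scipy.sparse.linalg.expm_multiply` without materializing the dense
exponential. Tiny negative entries from round-off are clipped and the
vector renormalized (relative change ~1e−16), so heat vectors always sum
to 1 within 1e−9 and have no entry below −1e−12.

## Stopping rule and the washout guard

Diffusion time is walked along a geometric schedule `t_k = 0.1 · 2^k`
(≤ 30 steps) and stopped when consecutive snapshots agree,
`‖H(t_k) − H(t_{k−1})‖₁ < 1e−6`.

A pure stability rule is, however, degenerate on a connected graph: by the
time doubling `t` changes the vector by less than 1e−6, the vector is
within about that distance of the uniform limit, where only the slowest
Laplacian eigenmode survives in the residual. Two consequences were
observed on the planted-module benchmark: (a) all nodes' permutation
p-values become functions of a single scalar (the projection of the seed
indicator on that one eigenvector), hence perfectly correlated — the
per-run fraction of "significant" nodes is then bimodal (≈0 or ≈1) instead
of ≈0.05 under the null; (b) screening power collapses for some generator
seeds. Diffusion-based prioritization is only informative *before* mixing
completes.

The stopping rule therefore carries a second condition, the **washout
guard** (`DiffusionConfig.washout_floor`, default 0.25): the walk stops at
the last snapshot whose L1 distance to the per-component uniform
distribution is at least the floor. At distance 0.25 roughly an eighth of
the heat mass still deviates from uniform and many eigenmodes remain
active, so p-values decorrelate across nodes and the permutation null is
calibrated (measured fraction of p < 0.05 ≈ 0.05 on structureless
networks). Setting the floor to 0 recovers the pure stability rule and the
uniform limit; a `NearUniformWarning` is emitted whenever the returned
vector is effectively uniform, because candidate ranking then rests on
numerically tiny residuals.

The chosen `t` is recorded and reused for all permutation replicates: heat
magnitudes are only comparable at equal diffusion time.

## The screen

- **Permutation test.** 500 seed sets of the actual size are drawn uniformly
  without replacement from all network nodes (the seeds themselves are not
  excluded; the effect is O(|S|/n)). `p(g)` is the fraction of replicates
  whose heat at `g` strictly exceeds the actual heat — a replicate tying
  exactly does not count. p-values are therefore multiples of 1/500 and
  exactly 0 is possible; an optional `(Heat_> + 1)/(n + 1)` estimator is
  available for users who prefer never reporting 0, off by default. The raw
  `p < 0.05` cutoff is applied per candidate with no multiple-testing
  correction, matching the method's definition; users wanting FDR control
  can apply it to the reported p-value column.
- **Association test.** `MAS(g)` is the maximum confidence over edges from
  `g` to the reference drivers (self excluded); 0 if there is none. The
  threshold (default 400) is inclusive.
- **Function test.** The neighborhood `G` of a gene is itself plus its
  interactors at confidence ≥ 400 (the same medium-confidence convention).
  For each functional term with member set `F`, the enrichment score is the
  −log10 upper-tail hypergeometric probability of drawing at least
  `|G ∩ F|` members of `F` in `|G|` draws from a universe of `N` genes
  (default `N` = network node count, overridable). The tail is evaluated in
  log space (`hypergeom.logsf`) and capped at 300 so that cosine
  similarities stay finite; zero overlap scores exactly 0. GO and KEGG
  catalogs are concatenated into one profile vector with a deterministic
  term order. `MFS(g)` is the maximum cosine similarity between `ES(g)` and
  any reference driver's profile, defined as 0 when either vector is
  all-zero; the threshold (default 0.3) is inclusive.

Stages run in order and later statistics are computed only for survivors of
earlier stages, so survivor counts are non-increasing by construction;
every candidate's row records the last stage it passed.

## Multi-level orchestration

All levels run under one shared configuration (single Laplacian, shared
spectral cache). Latent lists exclude each level's own seeds (the point is
*novel* candidates), and every unordered pair of levels is intersected —
`C(k, 2)` pairs for `k` levels. Identifiers are compared verbatim; no
Ensembl↔symbol mapping layer is provided. The interaction-confidence
summary counts, for each latent gene, the validated drivers adjacent at
confidence ≥ 400 / ≥ 700 / ≥ 900.

## Synthetic benchmark

The generator emulates the structure the method assumes: a planted
partition. Default spec: 200 nodes, one module of 20; within-module edge
probability 0.7 with confidences uniform on [700, 999]; background edge
probability 0.02 with confidences uniform on [150, 400]; each omics level
seeds 50% of a designated module; each module gets 2 annotation terms
covering 90% of its members, plus 5 background terms of 10 random genes.
Everything is a pure function of the spec (including its RNG seed) —
regeneration is byte-identical.

What it does *not* emulate: the heavy-tailed degree distribution of a real
interactome, correlated edge confidences, term-size distributions of real
GO/KEGG, or any mutation/expression signal. Passing tests demonstrate that
the machinery recovers planted structure under the model's own assumptions,
not that those assumptions hold for real tumor cohorts.

At the default spec, non-seed module members receive more mean heat than
background nodes in ≈99/100 generator seeds, and a two-level run over a
shared module yields a non-empty latent intersection; both are exercised by
the test suite and `scripts/acceptance.py` at desk-scale problem sizes
(100–200 nodes, 500 permutations, 100 generator seeds).

## Numerical and degenerate-case choices

- Candidate ordering: heat descending, identifier ascending on ties —
  deterministic outputs, byte-identical TSVs across runs.
- Seeds missing from the network: warn and renormalize over those present;
  error only if none remain.
- Empty candidate sets and empty latent lists are warnings, not errors
  (exit code 3 under `--strict` on the CLI).
- Hypergeometric inputs are validated (`M ≤ N`, `n ≤ N`); GMT terms with
  fewer than two distinct members are dropped at load time with a warning.
- Permutation RNG is a single `numpy` `default_rng(rng_seed)` stream;
  p-values are reproducible bit-for-bit and invariant to candidate order.

## Known limitations

- The permutation test's power depends on the chosen diffusion time; the
  washout guard keeps the default in an informative regime, but very dense
  or very small graphs may pass the floor at the first schedule point, in
  which case the near-uniform warning fires and results should be treated
  as uninformative.
- No GO-graph true-path propagation: terms are taken as flat sets.
- `raw` weight mode produces diffusion timescales ~1000× shorter than
  `scaled`; the default schedule still covers them (it spans 5 orders of
  magnitude) but the first informative snapshot may be coarse.
- Intersections are pairwise only; three- and four-level overlaps are not
  reported.
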