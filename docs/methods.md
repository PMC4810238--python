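# Methods

## Model and procedure

`plastclust` partitions a multi-proteome protein set so that clusters gather
similar sequences from different proteomes while proteins of one proteome
fall into the same cluster as rarely as possible. No metric assumptions are
made about the similarity — not even the triangle inequality — which is why
the method operates on a graph rather than on an embedding.

The similarity is the normalized raw score
`s(p, q) = 2·s₀(p,q) / (s₀(p,p) + s₀(q,q))`, with `s₀` a local-alignment raw
score. Self-normalization makes `s` length-comparable and puts identical
proteins exactly at 1; it is not bounded by 1 in pathological cases (a pair
score exceeding both self scores cannot occur with exact Smith–Waterman but
can with heuristic search output), so the library asserts `0 ≤ s` only and
logs values above 1 rather than failing.

The four stages and their reasoning:

1. **Base graph** under the expect threshold `E` discards hits that are
   plausibly spurious regardless of their score. The comparison direction is
   a deliberate, prominently-made decision: an edge is present iff
   expect ≤ E (standard search semantics). The opposite direction — keeping
   pairs whose expect value is at or above a threshold — would retain only
   poor hits and contradict the bidirectional-best-hit construction of the
   next stage, and is explicitly not what this library does.
2. **Sparsification** keeps an edge only when it is the per-proteome-pair
   maximum seen from both endpoints. Ties keep every achieving edge —
   dropping one arbitrarily would break symmetry. For a within-proteome edge
   only one maximum condition applies; since the condition is stated for an
   ordered pair but the edge is unordered, it is read symmetrically: the edge
   survives if it is the best within-proteome edge at either endpoint. Maxima are taken over base-graph edges, i.e. after the
   expect filter, keeping the stage order G₀ → G.
3. **Kruskal maximum-weight spanning forest**: edges in descending weight;
   among equal weights, same-proteome edges first (so paralog pairs attach
   directly rather than via another species), then lexicographic endpoint
   order purely for determinism. With positive weights the forest attains the
   maximum total weight over all forests of the sparse graph — verified
   against an exhaustive oracle in the test suite.
4. **Partitioning** cuts a tree at its minimum-weight edge when that weight
   is below `H` and the preservation criterion fails, and re-examines both
   halves. The criterion protects trees whose weakest link still looks like
   an orthologous family: the weakest edge spans two proteomes and each
   proteome's members form a connected subtree (paralogs attach to each
   other, not through a third species). The split test is evaluated exactly
   in that order: split only if `s < H` **and** the criterion fails.
   Minimum-edge ties break lexicographically by endpoint ids; the worklist
   order over trees cannot affect the result (trees never interact), which
   the suite checks by partitioning components independently.

Size-1 trees bypass the criterion (they have no minimum edge) and become
singletons. "Clusters" are the size-≥2 parts; singletons are reported
separately, and the run report distinguishes singletons that were isolated
already in the sparse graph from those added by partitioning.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `H` | partition threshold on normalized similarity | 0.60 | reference configuration |
| `E` | expect threshold for base-graph edges | 0.001 | reference configuration |
| `L` | similarity floor for sparse edges | 0 | reference configuration |
| scorer | `builtin_local` or `external_tabular` | builtin | see below |

All three are dimensionless; `H` and `L` live on the normalized-similarity
scale (1 = identical proteins).

## Scoring

The built-in scorer is Smith–Waterman under BLOSUM62 with affine gaps in the
usual protein-search convention (a gap of length k costs 11 + k), via
Biopython's `PairwiseAligner`. Selenocysteine (U) is scored as cysteine and
any residue outside the matrix alphabet as X. Because no database search is
involved, built-in expect values are a Karlin–Altschul stand-in,
`E = K·m·n·exp(−λS)` with the gapped BLOSUM62/11/1 constants (λ = 0.267,
K = 0.041) and the product of the two sequence lengths as search space; this
is adequate for thresholding but is not a BLAST reimplementation, and
full-scale numeric reproduction of search-tool output will drift with scorer
versions and parameters.

External tabular search output is symmetrized by keeping the best raw-score
hit per ordered pair, then the maximum raw score (and minimum expect) of the
two directions — maximum rather than minimum favors edge retention where the
two search directions disagree. Pairs lacking a self-hit for either endpoint
are dropped (normalization would be undefined) and counted.

## Synthetic data

The generator plants `n_families` random ancestral sequences (uniform
amino-acid frequencies — a non-realistic but sufficient null) and emits, per
species, a point-mutated copy with probability `presence_prob`, plus a
further-mutated paralog with probability `paralog_prob`. Substitutions are
drawn proportionally to the positive BLOSUM62 alternatives of the original
residue (uniform fallback for residues with none, e.g. G, P), so mutated
copies remain detectably similar at the stated divergence. Mutations are
substitutions only by default, keeping the built-in scorer's behavior
predictable; single-residue indels are available behind a flag.

Defaults — 10 species × 30 families, presence 0.9, paralog rate 0.1, mean
length 120 (Poisson), divergence 0.10 — emulate a modest plastid panel:
plastid proteomes are dominated by short ribosomal and photosystem proteins,
most families are near-universally present with occasional losses, and
within-proteome duplicates are uncommon. What the generator does *not*
emulate: tree-structured divergence (all copies diverge independently from
the ancestor), rate heterogeneity across sites and families, length
variation by indel accumulation, and the heavy-tailed family-size
distribution of real data. Passing the planted-recovery tests therefore
shows the pipeline separates families at realistic sequence divergence, not
that real-data cluster counts are reproduced; full-scale statistics on real
panels additionally depend on the exact external search configuration.

Recovery is scored by the adjusted Rand index between the planted partition
and the output partition (clusters plus singletons-as-parts), computed by
scikit-learn; per-family purity (largest fraction of a family in a single
part) is reported alongside.

## Numerical and design choices

- Edge-weight comparisons during sparsification use exact float equality:
  the maxima are elements of the compared set, so no tolerance is needed.
- Determinism everywhere: cluster ids are assigned by smallest member id,
  output rows sorted, Kruskal and min-edge ties broken lexicographically.
  Identical inputs and parameters give byte-identical outputs (manifests
  differ only in timestamp).
- Degenerate inputs: empty FASTA files, GenBank records without translated
  CDS, empty species lists and sub-4-residue query fragments are errors;
  proteins with no hits at all flow through as isolated nodes and emerge as
  singletons.
- Profile equality for grouping uses presence/absence (the species-set view
  of a profile); count-level comparison is available behind a flag.
- PC(*n*) — the number of clusters whose maximum per-species multiplicity is
  exactly *n* — is computed over clusters only, never singletons, so that
  Σₙ PC(n) equals the cluster count.
- The fragment query is an exact-substring search by default with an
  optional Hamming (substitution-only) tolerance, reported with match
  positions.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the planted-recovery study at
10 species × 30 families (≈ 290 proteins, ≈ 43 000 alignments per seed) over
20 seeds, the forest oracle on 200 random graphs of ≤ 8 nodes and ≤ 14 edges
(exhaustively enumerable), and the similarity exactness checks on 100 random
sequences. These sizes exercise every stage — including components that the
partition step must split into several clusters — while keeping a full run
in the minutes range on one CPU.

## Known limitations

- The built-in expect value is a per-pair stand-in, not database-corrected;
  thresholding behavior differs from a real search tool at the margins.
- No composition-based score adjustment, and no invocation of an external
  search binary from the library (feed its tabular output instead).
- Very divergent family members (normalized similarity below `H` without a
  protecting tree structure) are split off by design; the method trades
  recall for within-proteome precision.
- A full-scale plastid panel (dozens of proteomes) requires downloading the
  GenBank records and running an external all-vs-all search; the repository
  reproduces the method's properties on synthetic data only.
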