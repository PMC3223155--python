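# Methods

## Model and scoring

Each reference genome is a k-th order Markov chain over {A, C, G, T}.
Training counts every window of k+1 consecutive unambiguous bases: the
first k bases are the context, the last base the successor. For a gap-free
sequence of length L this yields exactly L − k transition counts. Windows
containing any non-ACGT IUPAC symbol are skipped without perturbing
downstream windows; no pseudocounts are added.

Conditional probabilities are normalised per context against the sum of
*outgoing* counts (not the raw k-mer occurrence count). The two differ only
at sequence ends — a terminal k-mer has no successor — and the outgoing sum
is what makes each context's observed probabilities sum to exactly one,
which the test suite asserts to 1e−9. Costs are negative **natural**
logarithms; a transition with count zero in a genome carries a flat
`missing_cost`, default 10. The default cost means an unseen transition is
as expensive as an observed one of probability e^−10 ≈ 4.5·10^−5, so a
handful of unseen transitions quickly disqualifies a genome without any
single one being an outright veto.

A read's score against a genome is the sum of its per-transition costs —
equivalently the dot product of the read's 4^(k+1) transition-count vector
with the genome's cost vector. Batching reads turns classification into one
dense (reads × 4^(k+1)) · (4^(k+1) × N) matrix product. The read is
assigned to the genome with the minimum score; ties break to the lowest
database row index, deterministically.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 5 | model order (bases of context); vectors have 4^(k+1) = 4096 cells |
| `missing_cost` | 10 | −log-scale penalty per transition unseen in a genome |
| `strand_policy` | `both` | train on each sequence plus its reverse complement |
| `batch_size` | 1024 | reads scored per matrix product; bounds memory |
| `backend` | `vectorized` | dense product; `reference` = per-cell loop (oracle), `accelerated` = sparse CSR product |

`k` is capped at 8 (4^9 float32 cells per genome ≈ 1 MiB; beyond that
memory and the sparsity of observed transitions both degrade). Order 5 is
the default because per-read cost grows as 4^(k+1)·N while accuracy
saturates once contexts are long enough to be genome-specific.

All replicons (chromosomes and plasmids) of one genome are pooled into a
single model; read sampling in the simulator is per genome. With
forward-only models, querying both orientations of a read and keeping the
smaller score recovers strand invariance; with the default `both` policy no
extra work is needed.

## Numerical choices

- The database matrix is stored — on disk and in memory — as little-endian
  float32 (4096·4 B per genome at k = 5), so save/load round-trips are
  bit-exact and incremental `add` equals a from-scratch rebuild exactly.
- Scores accumulate in float64 regardless of storage width; this keeps the
  argmin stable across backends and batch sizes. All three backends agree
  within 1e−4 relative tolerance (in practice they agree to float64
  round-off, since each cost cell is the same float32 value widened once).
- `−ln 1.0` is canonicalised from `-0.0` to `+0.0` so all costs are
  non-negative.
- Reads shorter than k+1 bases (or consisting only of ambiguous windows)
  have zero valid transitions; they are reported as `UNCLASSIFIED` with a
  NaN score rather than erroring or being silently dropped.

## Evaluation

Accuracy at a taxonomy rank is the fraction of reads whose predicted label
at that rank exactly matches the truth label. The denominator is **all**
reads: `UNCLASSIFIED` predictions and `NA` labels count as wrong, so
accuracy is comparable across parameter settings that change how many reads
are classifiable. Genome-level accuracy compares genome ids directly.
Composition profiles tally reads per label at a rank, with optional
truncation to the top N labels and an `OTHER` bucket, conserving the total.

## Synthetic data

The simulator draws each genome as a realization of a random order-3 Markov
chain: every context's transition row is sampled from a symmetric
Dirichlet(0.1), then the chain is walked from a uniform start context.
Small concentration makes rows sparse and genomes compositionally well
separated — a caricature of distinct bacterial species. The generator order
(3) deliberately differs from the default classifier order (5) so recovery
tests do not assume the model family matches the data-generating process.
Reads are sampled with uniform start positions and strands, with optional
i.i.d. substitution errors (default 0, matching an error-free fragment
design of a fixed number of fragments per replicon).

Synthetic lineages are generated, not real taxa: each genome gets its own
species/genus/family/order/class, and genera are grouped round-robin into
phyla (about five per phylum) so every rank of the evaluation path is
exercised.

The standard benchmark — 20 genomes of 100 kb, concentration 0.1, 50
zero-error reads per genome at 100/500/1000 bp, seed 42, k = 5 database —
runs in a few seconds on one CPU. On it, genome-level accuracy exceeds 0.95
at 500 and 1000 bp and rises with read length, which the acceptance suite
asserts.

What passing these tests shows: the scoring machinery is exact (matrix path
= per-transition oracle), the model is correctly normalised, and the method
separates compositionally distinct sources. What it does **not** show:
performance on real genomes, which share k-mer statistics through phylogeny
and horizontal transfer, contain repeats and low-complexity regions, and
are read with platform-specific error profiles (homopolymer indels are not
simulated at all). Accuracy on real communities, especially for sources
absent from the reference database, will be substantially lower than on
this fixture.

## Design notes

- Log base and penalty: the missing-transition constant 10 is applied in
  natural-log units, the same scale as the stored `−ln P` costs.
- `F(O_m)` as outgoing-sum (see above) rather than raw context occurrences;
  chosen for exact normalization.
- The accelerated backend is a CPU sparse (CSR) product exploiting the fact
  that a read touches at most l − k of the 4^(k+1) cells; it passes the
  same equivalence suite as the dense path. A GPU BLAS backend would slot
  in behind the same interface.
- The CLI config file uses TOML `key = value` pairs applied to every
  subcommand; explicit flags take precedence over the config, which takes
  precedence over built-in defaults.

## Known limitations

- No interpolated or variable-order models, no smoothing/pseudocounts: a
  genome either has seen a transition or pays the flat penalty.
- Seven fixed ranks (superkingdom…species); NCBI "no rank" nodes and
  LCA-style multi-assignment are out of scope.
- No confidence score on assignments — only the raw minimum cost and,
  optionally, the top-N genome list per read.
- Abundance estimates are raw read tallies; no genome-length or copy-number
  correction.
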