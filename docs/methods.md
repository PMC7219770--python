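# Methods

## Pairing model

A translating ribosome covers a footprint of roughly 15–45 nucleotides
of mRNA; the commonly accepted estimate is about 28 nt, i.e. nine
codons. We model the footprint as a sliding window of `w` codons
(accepted range 2–15, default 9; the sweep 2–11 covers the footprint
estimates) and say two codon positions `i < j` pair-compatible symbols
"within the window" iff `j − i ≤ w − 1`. This pairwise form is
equivalent to scanning every contiguous `w`-codon window, runs in
O(n·w), and handles genes shorter than the window without padding.

Three modes define what counts as a pair:

* **identical** — the same sense codon at both positions; the recorded
  symbol is the codon (≤ 61 possible symbols under table 1).
* **cotrna** — two *different* codons encoding the same residue; the
  symbol is the residue (≤ 20). Two identical codons never trigger this
  mode.
* **combined** — any two codons of the same residue; the symbol is the
  residue. Combined equals the union of the identical set (mapped
  through the genetic code) and the cotrna set.

Encoding is strictly binary: a symbol enters the gene's pairing set
once, regardless of how many times it pairs. Stop codons and codons
containing non-ACGT letters never pair, but their positions still count
toward pairwise distance (deleting them first would artificially shrink
distances across the gap).

## Input handling

One FASTA file per species, one record per gene. The ortholog key is
extracted from the header by a configurable rule: a `gene=` /
`[gene=...]` tag when present, otherwise the first whitespace-delimited
token. Records are validated (length divisible by three; terminal stop
stripped; internal stops drop the gene by default, with a keep-and-skip
policy available), records whose headers carry configurable
annotation-problem keywords (default `exception`, `partial`) are
dropped, and among records sharing a key only the longest CDS is kept
("longest isoform"; ties keep the first in file order, which makes the
selection deterministic and idempotent). Translation tables are the
standard NCBI ones via Biopython (default table 1; e.g. `--table 11`
for bacteria).

## Alignment-free distance

The species profile is the set of distinct nonempty gene motifs (sorted
symbol tuples). For profiles *a*, *b*:

    Dist = 1 − |a ∩ b| / min(|a|, |b|),

and the distance is snapped to 1.0 when either profile is empty or the
size ratio min/max is ≤ 5% (inclusive, since the guard is phrased as
"does not exceed"). The min-normalization makes the distance a
containment measure, not a metric; the triangle inequality is neither
assumed nor used. Both-empty pairs score 1.0 (no evidence of
similarity). Matrices serialize in square PHYLIP format (`%.6f`).

Trees are built by Saitou–Nei neighbor joining (scikit-bio's
implementation, negative branch lengths clamped to zero). NJ is the
default distance-to-tree method; nothing in the pipeline depends on
this particular choice and the tree-building step is isolated behind
`profiles_af.neighbor_joining`.

## Parsimony character matrix

Each (ortholog, symbol) with pairing in at least one species becomes a
column over {0, 1, ?}, '?' exactly where the species lacks the
ortholog. Filters follow a single linear pass: (1) keep columns whose
ortholog is called in ≥ 4 species and that show both states among
scored cells ("parsimony-informative" in the pipeline's sense — note
this admits autapomorphic columns; `--strict-informative` applies the
textbook ≥ 2-taxa-per-state rule); (2) remove species scoring fewer
than 5% of the retained columns ('?'-fraction based — coverage means
ortholog availability, not pairing presence); (3) abort the analysis as
a distinct "group not analyzable" outcome when fewer than 5% of the
input species survive. Columns are not re-filtered after species
removal unless `--refilter` asks for one extra pass. Export is TNT
`xread` plus a key file whose line *i* names column *i*; taxon names
are sanitized with an optional sidecar map for reversibility, and the
writer/reader pair round-trips matrices bit-exactly.

## Tree diagnostics

**Edge overlap.** Both trees are pruned to their shared leaf set (≥ 4
required) and compared as sets of non-trivial bipartitions, so rooted
and unrooted representations agree and polytomies contribute only the
splits they resolve. Directional percentages (shared/source,
shared/reference) are both reported; an undirectional headline is their
mean over defined directions (a star tree has no non-trivial splits and
yields a NaN direction). Multiple equally parsimonious source trees are
compared one by one and averaged.

**Parsimony length.** Minimum state changes for a binary character are
computed by a two-state Sankoff dynamic program with unit costs, which
equals the Fitch length on bifurcating trees and remains exact on
polytomies (where the sequential union/intersection heuristic is not).
'?' is the full ambiguity set {0, 1} and costs nothing; an all-'?'
column scores 0 steps. The DP is vectorized across columns.

**Retention index.** Per character, with `s` the observed steps, `m`
the minimum possible (1 when both states occur, else 0) and `g` the
maximum (`min(#0, #1)` over scored taxa — the tree-independent bound
attained on a star): RI = (g − s)/(g − m), defined only when g > m;
undefined characters are skipped and counted. Both the mean of
per-character RIs (the headline) and the ensemble RI
(Σg − Σs)/(Σg − Σm) are reported, since either convention is defensible.

**Permutation null.** The null hypothesis is "no association between
character states and tree placement": each of `n_perm` (default 1000)
iterations shuffles which species carries which matrix row while the
topology stays fixed — equivalent to shuffling leaf labels, because
tree leaves without matrix rows are fully ambiguous and contribute no
steps — and recomputes the mean RI. The empirical p-value uses the
add-one estimator (1 + #{null ≥ observed})/(1 + n_perm), so the
smallest attainable p is 1/(n_perm + 1). Seeded and bit-reproducible.

**Saturation.** Computed distances are paired with topological path
lengths (edge counts on the derooted reference tree); the saturation
fraction is the share of pairs at the ceiling 1.0, where divergence
information is destroyed.

## Simulator

The generator evolves one binary state per (ortholog, symbol) character
down a known tree: root states are Bernoulli(`root_pairing_prob`), and
each edge flips a state with the exact symmetric two-state
continuous-time Markov transition probability
`(1 − exp(−2·flip_rate·t))/2`, which is ~`flip_rate·t` for short
branches and tends to the stationary disagreement of ½ as paths grow —
so distances saturate gracefully rather than oscillating, which a
"probability of at least one event" formula would cause.

States are realized as coding sequences by block construction: each
target symbol becomes two adjacent codons that pair by design (the
codon doubled for identical mode; two distinct synonyms for cotrna,
which therefore draws symbols only from residues with ≥ 2 codons; a
doubled representative codon for combined), and the remaining length is
filled with codons rotating through `w` distinct codon/residue
families, so the same family never recurs within `w − 1` positions.
Filler families overlapping the target are used only when the alphabet
runs out and are harmless: any pairing they cause is of a symbol
already in the target. This makes realization exactly invertible —
`gene_pairing_set(realize(S)) = S` — which is the module's defining
property and is tested over random targets in every mode. Biological
realism of the filler sequence (codon usage, GC content, substitution
process) is explicitly not modeled; conclusions from passing tests
concern the pipeline's correctness and its behavior under the binary
conserved-character model, not the strength of pairing signal in real
genomes.

Defaults were chosen once as moderate-divergence study conditions:
random binary trees with branch lengths U(0.1, 1.0), 200 orthologs
(500 in the recovery runs), 8 candidate symbols per ortholog, root
pairing probability 0.5, 300-codon genes, flip rate 0.1 (0.05 for the
low-divergence recovery condition, under which pairwise profile
distances stay well below saturation). An optional `missingness`
parameter drops orthologs per species uniformly at random to exercise
'?' handling.

## Numerical and edge-case choices

* Window bounds 2–15 enforced everywhere (a pair needs two codons).
* Undefined statistics (R² under zero variance, RI with g = m,
  directional overlap of a star tree) are reported as NaN sentinels,
  never silently as 0.
* "Total pairing events" for the length-correlation check counts
  unordered in-window position pairs (the most direct reading); the
  distinct-symbol count is `|gene_pairing_set|`. The event count grows
  linearly with gene length by construction, the distinct count is
  bounded by the alphabet — the contrast the statistic exists to show.
* Problem sizes in the test suite and acceptance script (1000-gene
  oracle corpus, 16 species × 500 orthologs, 200 permutations) were
  chosen to give stable stochastic outcomes at interactive runtimes.

## Known limitations

* Ortholog matching is exact string equality of header-derived keys; no
  sequence-based orthology inference.
* Co-tRNA mode treats all synonymous codons as sharing a tRNA; real
  wobble rules and tRNA gene copy numbers are not modeled.
* The ete3 `compare` module, TNT's own tree search, and
  maximum-likelihood baselines are out of scope; the package exports
  TNT input and scores character fit itself.
* The distance is not a metric; methods that require metricity (e.g.
  some fast NJ variants) should not assume it.
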