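# codonpairing

Phylogenomics from **codon pairing**: when a coding sequence needs the
same tRNA (or a synonymous one) twice within a ribosome footprint, the
tRNA can be recharged and reused before it diffuses away. Which codons
show this within-footprint reuse is a heritable, alignment-free genomic
feature. This package detects codon pairing in per-species CDS FASTA
files and turns it into phylogenetic evidence along two routes:

1. **Alignment-free distances.** Each gene contributes a *pairing motif*
   — the sorted set of symbols (codons or amino-acid residues) that pair
   anywhere in the gene within a sliding window of `w` codons. A species
   profile is its set of distinct motifs, and the distance between
   species with profiles *a* and *b* is

       Dist(A, B) = 1 − |a ∩ b| / min(|a|, |b|)

   with pairs snapped to the maximum distance 1.0 when the profile-size
   ratio min/max does not exceed 5% (a small-genome guard). The matrix
   feeds neighbor-joining.

2. **Parsimony characters.** Across species sharing orthologs, each
   (ortholog, symbol) becomes a binary character: `1` if the symbol pairs
   in that species' ortholog, `0` if not, `?` if the ortholog is absent.
   Characters are filtered (ortholog in ≥ 4 species, both states
   present, species covering ≥ 5% of characters, group analyzable only
   when ≥ 5% of species pass) and exported as a TNT `xread` matrix with
   an ordered key file.

Three pairing modes are supported: `identical` (same codon twice within
the window), `cotrna` (two *different* codons encoding the same residue)
and `combined` (any two codons of the same residue; the default).
Tree diagnostics include percent bipartition overlap between trees,
the retention index of a character matrix on a reference topology with a
leaf-label permutation null, and a distance-saturation profile. A
simulator generates species with phylogenetically conserved pairing
signal along a known tree and realizes them as FASTA, so every stage is
testable end to end.

## Worked example

Simulate 8 species with conserved pairing signal, recover the tree
alignment-free, and compare it with the truth:

```bash
codonpair simulate --species 8 --orthologs 300 --flip-rate 0.05 \
    --window 9 --mode combined --seed 42 --out demo/
codonpair af -id demo/ --mode combined --window 9 \
    --out-matrix demo/dist.phylip --out-tree demo/nj.nwk
codonpair compare --source demo/nj.nwk --reference demo/true_tree.nwk
```

The last command prints:

```json
{
  "shared_bipartitions": 4,
  "n_source": 5,
  "n_reference": 5,
  "pct_source_in_ref": 80.0,
  "pct_ref_in_source": 80.0,
  "mean_pct": 80.0
}
```

i.e. 4 of the 5 non-trivial bipartitions of the recovered
neighbor-joining tree match the generating topology (80% overlap in both
directions; at this modest size one short internal edge is lost to
sampling noise — 500 orthologs recover 16-species trees at ≥ 90%, see
below). The parsimony route on the same data:

```bash
codonpair matrix -id demo/ -o demo/m.tnt -oc demo/keys.tsv \
    --mode combined --window 9
codonpair ri --tree demo/true_tree.nwk --matrix demo/m.tnt \
    --keys demo/keys.tsv --perms 200 --seed 42
```

prints

```json
{
  "mean_ri": 0.761640798226164,
  "ensemble_ri": 0.7936962750716332,
  "n_characters": 949,
  "n_skipped": 498,
  "p_value": 0.004975124378109453,
  "n_perm": 200,
  "null_mean": 0.12279379157427936,
  "seed": 42
}
```

a mean retention index of 0.76 over 949 informative characters against a
permutation null of 0.12, at the minimal empirical p-value
`1/201 ≈ 0.005`: the pairing characters carry strong phylogenetic signal
on the true tree and essentially none on a randomly relabelled one.

The same functionality is available as a library
(`codonpairing.gene_pairing_set`, `build_profile`, `distance_matrix`,
`neighbor_joining`, `assemble_raw_matrix`, `retention_index`, ...); see
the module docstrings.

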