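# coevocontacts

Tools for asking a deceptively simple question in protein structural
bioinformatics: **what counts as a residue–residue contact?**

Evolutionary coupling (EC) analyses score pairs of columns in a multiple
sequence alignment for direct covariation and are benchmarked by how many of
their top-ranked pairs are "true" contacts in a solved structure. But the
truth depends on the reference point used to measure residue–residue
distances. This package implements five standard contact definitions and the
machinery to compare them — and to measure, on both real and synthetic data,
which definition ranked couplings actually recover.

## Contact definitions

For residues *i*, *j* in a cleaned single-chain structure (consecutively
numbered 1..L, heavy atoms only), the distance d(i, j) is measured as:

| Method | Reference |
|---|---|
| `CA` | Cα–Cα distance |
| `CB` | Cβ–Cβ distance (glycine: Cα) |
| `SC_CENTER` | distance between side-chain geometric centers — the unweighted mean of non-backbone heavy atoms, Cβ included, Cα excluded (glycine: Cα) |
| `MIN_ALL` | minimum over all heavy-atom pairs |
| `MIN_SC` | minimum over side-chain heavy-atom pairs (glycine contributes Cα) |

Contacts are pairs with chain separation j − i ≥ 12 and d(i, j) ≤ cutoff.
Cutoffs are either fixed (8 Å for Cα; 7.6 / 7.5 Å for Cβ / side-chain
centers; 4.5 Å for minimum-distance methods) or *count-matched*: given the n
contacts found at the Cα 8 Å cutoff, each other method takes its n closest
eligible pairs, so per-protein accuracies are directly comparable.

Ranked couplings (from an external program's L×L matrix, or from the built-in
mutual-information scorer with average product correction and 80%-identity
sequence reweighting) are evaluated by PPV@L/2 — the fraction of the top
⌊L/2⌋ long-range couplings that are contacts — and by average precision over
the full ranking. Pair side-chain *orientations* are classified by the π/2
vector test (side chain of *a* "points toward" *b* iff the angle between
Cα→SC-center and Cα→Cα_b is < π/2) into both-toward / mixed / both-away.

A synthetic-data module generates compact self-avoiding toy structures with
pseudo side chains and alignments whose covariation is *planted* at the
structure's contacts with known strength c — with probability c the amino
acid at one site of a pair determines the other through a fixed random
bijection. The planted mutual information has the closed form

    MI(c) = (c + (1−c)/q)·ln(cq + 1−c) + (1−c)(1−1/q)·ln(1−c),  q = 20,

which serves as an analytic oracle for the scoring stack.

## Worked example

Generate a planted dataset (L = 100, N = 3000 sequences, c = 0.7, planted on
side-chain-center contacts) and run the full comparison:

```bash
coevocontacts synth --out demo -L 100 -N 3000 -c 0.7 --seed 1
coevocontacts pipeline demo/synth.pdb --alignment demo/synth.fasta \
    --out demo/report --seed 1
```

Key numbers from the report (seed 1):

```
L 100, contacts per method (count-matched): 345
SC_CENTER effective cutoff: 7.94 Å
CA vs SC_CENTER contact overlap: 0.71, distance Spearman ρ: 0.939
PPV@L/2:  CA 0.68   CB 0.80   SC_CENTER 0.96   MIN_ALL 0.80   MIN_SC 0.94
both-toward fraction: all pairs 0.219, top-0.25L couplings 0.400
```

Although Cα- and side-chain-center distances are almost perfectly rank
correlated (ρ ≈ 0.94), the contact maps they induce overlap only ~70% — and
the same ranked couplings recover side-chain-defined contacts near-perfectly
(PPV 0.96) while plateauing far lower against backbone-based definitions
(0.68). Minimum side-chain atomic distance behaves like the side-chain
center; Cβ sits in between. Top-ranked couplings are strongly enriched in
pairs whose side chains point toward each other (0.40 vs the 0.22 all-pairs
baseline). This is the expected signature when pairwise covariation lives at
side-chain interactions, and it is why EC benchmarks against Cα-defined
contacts understate algorithm accuracy.

The same machinery runs on real data: `coevocontacts clean` a PDB chain,
then `coevocontacts eval structure.pdb --alignment homologs.fasta` (or
`--matrix couplings.mat` for CCMpred-style output).

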