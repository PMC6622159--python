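# Methods

This note documents the models, conventions and numerical choices behind
`coevocontacts`, in the order data flows through the package.

## Structure cleaning

A structure is reduced to one chain of one model: HETATM groups (waters,
ligands) are dropped, hydrogens/deuteriums removed, and for disordered atoms
exactly one alternate location is kept — the highest-occupancy conformer,
with ties broken by altloc identifier order so the result is deterministic.
Residues are renumbered consecutively 1..L; every retained residue must be
one of the 20 standard amino acids and contain a Cα. Selenomethionine and
selenocysteine can optionally be mapped to MET/CYS (`map_nonstandard`);
any other non-standard residue is a hard error naming the residue, because
silently skipping residues would shift the numbering that every downstream
pair index depends on.

The package deliberately does **not** rebuild missing atoms. A non-glycine
residue with no side-chain heavy atoms is an error by default; the
`missing_side_chain="ca"` policy instead substitutes the Cα position (with a
warning). The default is strict because a silent fallback changes contact
maps: a Cα stand-in systematically shortens apparent side-chain distances
for long side chains. OXT is treated as backbone (a terminal backbone
oxygen). Coordinates are used exactly as given; no minimisation or
regularisation is applied.

## Atom subsets and the glycine convention

Backbone = {N, Cα, C, O, OXT}; side chain = all other heavy atoms, so Cβ is
a side-chain atom. Glycine has no side-chain heavy atom and uses Cα as its
side-chain representative: its side-chain subset is [Cα], its Cβ and
side-chain-center reference points are the Cα coordinate, and it contributes
Cα to minimum-side-chain distances. This is the single documented exception
to the backbone/side-chain partition and is asserted as such in the tests.

## Distances, contacts, matched counts

Only pairs with chain separation j − i ≥ 12 are considered throughout
("at least 12 residues apart" is read inclusively: the pair (1, 13) is
eligible — an off-by-one here changes every contact count, so the choice is
pinned by a dedicated test). Distances are compared to cutoffs with ≤
(inclusive boundary). Point-method distance matrices are exact Euclidean
metrics and satisfy the triangle inequality; the minimum-distance methods
need not, and MIN_ALL ≤ MIN_SC always, both checked as properties.

Count-matching selects the n closest eligible pairs under a method, where n
is the number of Cα 8 Å contacts; the effective cutoff reported is the n-th
smallest eligible distance. Ties at the boundary are resolved by sorting on
(distance, i, j), which makes the selected set platform-independent and
|pairs| = n exact under any tie pattern. Fixed-cutoff mode instead uses 8 Å
(Cα), 7.6 Å (Cβ), 7.5 Å (side-chain center) and 4.5 Å (minimum-distance
methods); the point-method values sit at the middle of the matched-cutoff
distributions seen in practice.

Distance-matrix agreement between methods is summarised by Spearman rank
correlation over the eligible-pair distance vectors; contact-map agreement
by the overlap fraction |A ∩ B| / |A|, defined only for count-matched maps
(comparing overlap between maps of different sizes conflates definition
disagreement with base-rate differences, so it is an error).

## Side-chain orientation

Residue a points toward residue b iff the angle between (Cα_a → side-chain
center_a) and (Cα_a → Cα_b) is strictly less than π/2 — equivalently the dot
product is strictly positive. Repeating from b gives three symmetric pair
classes: both-toward (i), mixed (ii), both-away (iii). Glycine's orientation
vector is zero and the angle undefined; the strict inequality then
classifies glycine as "not pointing toward", so every pair remains
classifiable. Summaries can alternatively exclude glycine-containing pairs
(`exclude_glycine`); with ~5% glycine the two conventions differ by roughly
0.02 in the both-toward fraction, which is worth remembering when comparing
against the 1/4–1/2–1/4 isotropic expectation.

## Coupling scores

The built-in scorer is intentionally the simplest thing that exposes the
covariation interface: weighted mutual information over a 21-state alphabet
(20 amino acids + gap; gaps are counted as a state so every column keeps the
same effective depth) with average product correction,

    S_ij = MI_ij − (M_i · M_j) / M̄ ,

where M_i is the mean MI of column i against all others and M̄ the grand
mean. Sequences are reweighted by local redundancy: weight 1/k for a
sequence with k neighbours at ≥ 80% identity (self included). Frequencies
are smoothed with a pseudocount of λ = 0.5 per state per column on
single-site counts and λ/21 per joint cell, which makes pair marginals
reduce exactly to single-site frequencies and keeps the plug-in MI
non-negative. It is not a pseudolikelihood or inverse-covariance method and
will not match their empirical accuracy on natural alignments; those
programs' outputs are ingested instead through the L×L matrix reader
(asymmetric input symmetrised by elementwise maximum) or the 1-based
"i j score" edge-list reader.

Ranking sorts eligible pairs (same j − i ≥ 12 restriction as contacts, so
numerator and denominator of PPV refer to the same pair universe) by score
descending with deterministic (i, j) tie-break. PPV@k uses k = ⌊L/2⌋ by
default. Average precision is computed directly from this deterministic
ranking as Σ_k (R_k − R_{k−1}) P_k — not from a library routine, whose tie
handling differs; the library value is instead used as an independent
cross-check on tie-free instances. Paired per-protein PPVs are compared with
the two-sided Wilcoxon signed-rank test (exact null below n = 25 when no
differences are zero, normal approximation otherwise) and summarised by the
median of per-protein ratios, reported as a percent increase. When the two
vectors are identical the test is degenerate; the comparison then reports
statistic 0 and p = 1 with a warning rather than failing, since the effect
size (0%) is still well defined.

## Synthetic data: what it emulates, and what it does not

The generator replaces two things at desk scale: a benchmark set of solved
structures, and stability-constrained evolutionary simulation as a source of
sequences with planted covariation.

**Structures.** A self-avoiding Cα walk (3.8 Å steps, 4.0 Å non-consecutive
clash distance, backtracking before whole-chain restart) is confined to a
sphere of ~90 Å³ per residue. Confinement makes the chain fold back on
itself, producing 2–3 long-range contacts per residue and contact graphs
that touch nearly every site — the contact statistics of a globular domain.
The sphere volume is smaller than an all-atom protein's because the pseudo
side chains carry only 1–3 atoms. Each non-glycine residue gets a Cβ at
1.5 Å and 1–3 further pseudo-atoms extending up to 1.5–4 Å along a
per-residue direction drawn isotropically by default; `packing_bias > 0`
optionally tilts directions toward the residue's sequence-distant spatial
neighbourhood, mimicking buried side-chain packing. With isotropic
directions, the all-pairs both-toward fraction is ~0.22 with 5% glycine
(0.25 without), which happens to sit at the baseline observed for real
globular proteins. Minimal N/C/O backbone atoms are placed along the chain
so that all five contact definitions are exercised.

**Alignments.** Sites are paired one-to-one on the structure's
(matched-count) contact graph by a maximum-cardinality matching; each site
belongs to at most one planted pair, so the joint distribution of the
alignment is exactly pairwise and analytically tractable — no Potts Gibbs
sampling is needed, and the mutual information of a planted pair is the
closed-form MI(c) mixture formula. A maximum matching (rather than an
arbitrary greedy pass) is used because near-perfect recovery of a contact
map by top-L/2 couplings presupposes that covariation reaches most of the
map; greedy pairing strands 10–30% of pairable sites and caps the
recoverable signal well below that of real contact graphs. Within a pair,
with probability c the state at one site determines the other through a
fixed random bijection; otherwise both are independent and uniform over
q = 20 amino acids. Sequences are i.i.d. — no phylogeny, no gaps, no
insertions — and the reference row is row 0.

**What passing on synthetic data shows.** That the full stack — cleaning,
geometry, scoring, ranking, evaluation — correctly localises pairwise
covariation and correctly distinguishes contact definitions when covariation
is planted at one of them. It does not show empirical accuracy on natural
alignments, which is limited by phylogeny, gap structure, alignment depth
and the scorer itself; the generator deliberately removes all of those
effects. The coupling strength c plays the role of selection strength in
stability-constrained simulation only qualitatively.

**Default study conditions.** L = 100, N = 3000, c = 0.7, planted on
side-chain-center contacts. Under these conditions PPV@L/2 against the
planted definition is ≥ 0.9 with a ≥ 0.05 margin over Cα-defined contacts
across seeds, and recovery saturates quickly in N; the rising
accuracy-vs-depth trend is visible in the weak-coupling family (c ≈ 0.2),
where N = 100 is still data-limited.

## Problem sizes used in the checks

Tests and the acceptance script run at L = 40–100 and N = 100–5000: analytic
MI comparisons use N = 5000, where the finite-sample plug-in MI bias
(≈ (q−1)²/2N ≈ 0.036 nats) sits inside the 0.05-nat band; recovery checks use
the default conditions above; ensemble medians use 8 structures at N = 1000.
Statistical expectations over correlated pair sets (orientation fractions)
are tested against replicate-structure means with σ estimated across
replicates, not binomial counts, because pairs sharing a residue are
strongly dependent.

## Known limitations

* The MI+APC scorer is a stand-in: adequate for planted covariation,
  substantially weaker than pseudolikelihood methods on natural alignments.
* Toy structures have no secondary structure, no amino-acid-dependent
  side-chain geometry, and no correlation between sequence and structure.
* Orientation classification reduces a side chain to one vector; long
  flexible side chains are poorly summarised by their geometric center.
* Single chains only: no homo-oligomer contacts, no inter-chain couplings,
  first model only for multi-model entries, no mmCIF input, no structure
  repair.
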