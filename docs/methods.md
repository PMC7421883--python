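# Methods

This note documents the models, parameters and numerical choices behind
`pksnrps`, what the synthetic benchmark does and does not demonstrate, and
the design decisions taken where the method left room.

## Hybrid identification

A PKS–NRPS hybrid candidate is a protein carrying ketosynthase (PF00109),
acyltransferase (PF00698) **and** condensation (PF00668) domain hits
(dataset 1); the condensation domain is the discriminator against
LovC-type highly reducing PKSs, which share the PKS module but lack the
NRPS module. The length filter (> 3,000 aa, strict) removes remaining
single-module enzymes (dataset 2). Dereplication (dataset 3) collapses
near-identical hybrids within *taxonomically related* strains.

Choices made here:

* **"Taxonomically related" = same genus.** The concept is routinely left
  vague in mining studies; genus-level collapsing is the conservative
  reading (species-level collapse removes fewer sequences and is available
  by supplying species-resolved taxonomy and treating each species as its
  own genus key).
* **Ortholog criterion** is p-distance < 0.05, single linkage, because the
  exclusion is naturally phrased pairwise. The cluster representative is
  the longest sequence (ties: smallest id) — longest because fragmentary
  gene models are the dominant artifact in draft fungal assemblies.
* **Strictness**: "> 3,000 aa" and "> 40%" and "< 0.05" are all strict
  inequalities; boundary values fall outside.

## Domain scanning

The built-in scanner is deliberately simple: each domain family has a
position-specific scoring matrix derived from a consensus block (the
BLOSUM62 column of the consensus residue at each position), scored over
every window of the protein; non-overlapping windows above an absolute
threshold (0.4 × the consensus self-score) are hits. This is calibrated
for the packaged consensus blocks and the synthetic cohorts: at 30%
per-position divergence a true block still scores ≈ 0.6 × self-score,
while the maximum window score of an unrelated random protein stays far
below 0 (measured in the test suite). Real Pfam/HMMER scans are richer
than any single-consensus PSSM; users with hmmscan output import it
through the `import_table` backend (TSV: protein_id, domain_id, start,
end, score), which validates coordinates and passes hits through.

## Distances and alignments

* **p-distance** (mismatches / aligned columns with both residues
  non-gap), computed on a global pairwise alignment. Columns containing X
  are excluded from numerator and denominator; X never counts as a match
  anywhere in the package. The default global aligner is edit-distance
  optimal (edlib); a BLOSUM62/affine-gap aligner (open −11, extend −1) is
  available as `backend="blosum"`. The p-distance is a function of the
  aligned columns, not the scoring scheme, and the two backends agree to
  < 0.01 on homologous pairs (tested); the edit-distance backend is ~100×
  faster on 3-kaa proteins, which makes all-vs-all matrices practical.
  Optimal global alignments are not unique, so `p_distance` canonicalizes
  the argument order internally — symmetry holds by construction.
* **Local identity** for the modification-enzyme search is Smith–Waterman
  with BLOSUM62/affine gaps; identity = matches / alignment columns (gap
  columns count in the denominator), the BLAST report convention. Ties in
  the traceback resolve to the first alignment in Biopython's
  deterministic order.
* **ME presence** additionally requires that the alignment cover ≥ 50% of
  the query (`me_min_query_coverage`). Best-scoring local blocks between
  unrelated ~350-aa proteins regularly exceed 40% identity over 20–50
  columns; BLAST discards such hits by E-value, which this package does
  not model, so query coverage serves as the significance proxy. The
  presence rule is therefore: identity > 40 (strict) **and** coverage ≥ 0.5.
  Presence remains monotone in the identity cutoff.
* An external multiple alignment (e.g. MAFFT) can replace the built-in
  pairwise route: `build_distance_matrix(..., mode="msa",
  alignment_path=...)` computes the same column-wise p-distances on the
  provided alignment.

## Tree construction and clade placement

UPGMA (average linkage) with size-weighted cluster means; a merge at
distance *d* places the node at height *d*/2, so the tree is ultrametric
by construction (verified to 1e-9). Tie-breaking is explicit: among
minimal-distance pairs, merge the pair whose smallest-leaf-label key is
lexicographically least. The implementation is cross-checked in the test
suite against a brute-force oracle (cluster means recomputed from the
original matrix each step) and against scipy's average-linkage heights.

Major-clade assignment is nearest-reference by path distance in the tree:
each query hybrid takes the clade label (Ia, Ib, II, III) of its nearest
reference leaf, with ties to the smallest reference id; a query nearest to
an outgroup (NR-PKS/FAS) is "unplaced". Monophyly-based assignment was
considered and rejected as the default because single aberrant leaves
(fragmentary hybrids) break monophyly long before they change the nearest
reference.

## Biosynthetic gene clusters and the decision table

The BGC is the 20-kbp flanking window anchored at the hybrid gene's
*boundaries* (start − 20,000 to end + 20,000, 1-based inclusive, clipped
at 1); any ≥ 1 bp overlap makes a gene a member. Coordinates stay in GFF3
convention throughout — no half-open translation at either end.

Level I reads the putative Knoevenagelase (pKN): its absence marks the
core-I route (the DKC domain performs a Dieckmann condensation to a
tetramic acid), its presence the core-II route (reductive release, then
Knoevenagel condensation to a pyrrolinone). Tree placement is primary and
the pKN state is a consistency check: a clade-II hybrid without pKN keeps
its tree clade but carries a recorded warning, never a silent override.
Clade III admits both states.

Level II matches the profile against the packaged decision table
(`data/decision_table.tsv`, human-editable). Matching rules must agree on
Level-I clade, pKN and t-ER flags ("+/−" entries are encoded `either`),
contain all required MEs (Diels-Alderase requirements match on subtype;
`IIβ` matches both IIβ-1 and IIβ-2) and no forbidden ME. The most
specific rule (largest required set) wins; residual ties resolve by tree
proximity to each rule's reference hybrid, then lexicographically.

Three deliberate additions to a literal enzyme table:

* **Tenellin-clade rule forbids DAase** — otherwise every leporin or
  illicicolin profile (expandase + DAase) would also satisfy the plain
  expandase rule.
* **The fusaridione rule has an empty enzyme signature** and is accepted
  only when the hybrid's nearest reference neighborhood is the
  fusaridione clade itself; without the gate it would absorb every sparse
  clade-Ib profile.
* **Chaetoglobosin vs cytochalasin** share the signature {pKN, t-ER,
  DAase IIβ}; a pure enzyme table cannot separate them, so the tie always
  resolves by tree proximity. This is a documented limitation, not a
  defect of the implementation.

BGCs matching no rule are labelled with the nearest predicted-clade
neighborhood (11 packaged anchor labels) or "unclassified". Exactly one
of known/predicted/unclassified holds per BGC, and the evidence string
names the decisive rule or fallback path.

## Diels-Alderase typing

Type I DAases carry a SAM-binding motif; type II do not. The motif is
detected with the same PSSM machinery (threshold 0.5 × self-score); the
subclade (Iα, Iβ, IIα, IIβ-1 macrocycle-forming, IIβ-2 decalin-forming)
is the label of the best-identity reference *of the detected type*, among
references aligned at > 40% identity with coverage. When the motif and the
best reference disagree the subclade is left unknown and the conflict
flagged. Packaged reference labels: Iα LepI; Iβ IccD; IIα EqxF, Fsa2,
Phm7, Tas3; IIβ-1 CcsF, CHGG_01241; IIβ-2 PoxQ, MycB. The IIβ-1/IIβ-2
split follows the ring chemistry of the products associated with each
enzyme (macrocyclic cytochalasan-type vs decalin-forming).

## Scaffold prediction

A pure function of (clade label, ME profile): pKN absent → tetramic acid;
pKN present → pyrrolinone; expandase present → 2-pyridone (oxidative ring
expansion of the tetramic acid); clade III-B → tetronic acid override.
Ring annotations from the DAase subtype: IIα/IIβ-2 decalin, IIβ-1
macrocycle, Iα/Iβ pyridone polycycle. Absence of a DAase does not imply a
linear product (spontaneous cycloadditions exist), so "none" is an
annotation about the BGC, not the molecule.

## Summary arithmetic

Per-clade percentages are status-count / clade-row-total, rounded half-up
to integers (42.5 → 43). Totals are recomputed from the per-clade rows;
where historical summaries of this analysis report a total row
inconsistent with its own column sums, this package reports its own
arithmetic. The chemical-space estimate is (known + predicted groups) ×
`derivatives_per_group` (default 100, the order of magnitude suggested by
large NP families such as the > 300 known cytochalasans).

## The packaged reference bundle

Reference proteins (18 characterized hybrids, 11 predicted-clade anchors,
19 NR-PKS + 6 FAS outgroups, one ME query per category, 10 labelled
DAases) are synthetic stand-ins generated deterministically from a fixed,
versioned seed; real database proteins are not redistributed. The
synthetic genealogy is a divergence ladder: one hybrid ancestor (domain
blocks + linkers, 3,150 aa), major-clade ancestors at 18% per-position
divergence, clade references at a further 8%; NR-PKS outgroups share
diverged KS/AT/ACP blocks but no NRPS module; DAases diverge type →
subclade → reference at 15%/10%/7% with the SAM motif spliced into the
type-I lineage. These rates were chosen once so that within-clade,
between-clade and outgroup distances are well separated on the p-distance
scale (≈ 0.09 / 0.25 / > 0.5) — comfortably clear of the 0.05
dereplication cutoff and the nearest-reference decision boundaries. A
user-supplied bundle directory (FASTA + label TSVs + manifest) replaces
the default wholesale.

## What the synthetic benchmark shows — and what it does not

The generator plants, per template: a hybrid gene mutated from the
clade's reference, the clade's key-ME genes within the 20-kbp window,
decoy genes inside and outside the window, and (by default) one
HR-PKS-like contig that the condensation screen must reject. Mutation is
i.i.d. per-position substitution; coordinates use 3 bp per residue; each
planted BGC gets its own assembly and genus so dereplication is exercised
separately from recovery.

Passing the benchmark therefore demonstrates that the machinery is
correct and self-consistent: filters enforce their boundaries, the tree
places queries with their generating clade, profiles recover planted
enzymes, and the decision table reproduces the generating template at the
stated divergence. It does **not** demonstrate performance on real
genomes, where domain architectures vary, gene models are fragmentary,
tailoring enzymes are shared promiscuously between cluster families, and
evolutionary divergence is neither i.i.d. nor uniform across sites. The
published clade census (884 hybrids etc.) depends on a specific database
snapshot and is out of scope here.

## Problem sizes and determinism

The shipped tests and the acceptance script use cohorts of 18 BGCs (one
per template, rates 0/0.05/0.15) and 100 BGCs (all templates, rate 0.05);
these sizes give stable recovery estimates while keeping an all-vs-all
distance matrix of ~150 sequences, which is where the pipeline spends
most of its time. Every stochastic step (bundle generation, cohort
generation, mutation) runs off an explicit seed; rerunning any stage with
the same configuration and seed is byte-identical, and the per-run
provenance file records versions, thresholds and seed.

## Known limitations

* P450 subtype categories are distinguished only by which reference query
  scores best; real discrimination would need clade-aware profiles.
* Predicted clades are assigned by tree neighborhood alone; no conserved
  enzyme signature is claimed for them.
* The 40% identity cutoff is applied to the local alignment (with the
  coverage condition above); identity over the full query is a stricter
  alternative not used here.
* Cluster boundaries are a fixed window, not inferred; synteny and gene
  orientation are ignored.
* The off-loading-domain route (DKC vs R) is inferred from the pKN gene,
  not from domain-internal residues.
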