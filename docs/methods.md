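# Methods

## The screening model

The pipeline decides, per candidate protein, whether it is a putative
Mn(II)-oxidizing multicopper oxidase (MCO).  The decision is a
conjunction of four criteria evaluated in a fixed order with
short-circuiting; criteria after the first failure are reported as
`NA` (not evaluated).  The reference database drives everything: it
must contain at least two POSITIVE entries (known Mn-oxidizing genes,
with all four copper-site labels annotated when the family is MCO), one
NEGATIVE (an MCO without Mn-oxidation evidence) and one OUTGROUP.

### Criterion 1 — homology

"Homology" is operationalized as the percent identity of the best
Smith–Waterman local alignment against each POSITIVE reference.  This is
the only computable reading of a >30 % homology cut applied to BLASTP
output: identity of the highest-scoring local alignment (HSP), with the
gap-inclusive column denominator (BLAST convention;
`AlignmentResult.percent_identity(include_gap_columns=False)` gives the
alternative).  The bound is strict — exactly 30.0 % fails.  Scoring is
BLOSUM62 with affine gap cost 11 + k (BLASTP protein defaults); the
matrix ships as the standard NCBI text file, with the `X` row and column
overridden to 0 so an unknown residue neither helps nor hurts.  No
e-value is computed: the criterion is an identity threshold, not a
database-scaled significance.

The dynamic programming runs on Biopython's `PairwiseAligner`.  Among
co-optimal alignments the first alignment in the aligner's canonical
enumeration order is used; this makes every downstream quantity
deterministic.  One consequence: the match count of co-optimal global
alignments can depend on operand order, so `pairwise_distance`
canonicalizes operand order before aligning to keep distances exactly
symmetric.

The best hit (ties: higher score, then lexicographically smaller
ref_id) becomes the candidate's *assigned* reference, fixed here and
reused by criteria 3 and 4.

### Criterion 2 — domain compatibility

A profile-HMM search against an external domain database is replaced by
a self-contained position-specific scoring matrix (PSSM) over the
POSITIVE references, anchored on the longest one (ties: smallest
ref_id).  Each reference is globally aligned to the anchor;
residue-residue columns accumulate counts; columns where more than half
of the references are gapped are dropped.  The score of letter *a* at a
column with count *n_a* over *N* observations is

    log( ((n_a + pc·f_a) / (N + pc)) / f_a )

with background *f* the published BLOSUM62 marginal frequencies and
pseudocount mass pc = 1 by default (as pc → ∞ all scores shrink to 0).
Note the background is non-uniform, so two letters observed equally
often in a column get slightly different scores — this is intended:
rarer residues are stronger evidence.

A candidate is scored by globally aligning it to the anchor and summing
column log-odds over residue-residue columns (X contributes 0; every
gap column contributes a fixed −1.0).  Significance is a
composition-preserving permutation null: n_perm uniform residue
permutations of the candidate, each realigned and rescored, and

    p = (1 + #{shuffled score ≥ observed}) / (1 + n_perm),   pass iff p ≤ α.

Defaults α = 0.005, n_perm = 999.  The external database's 10⁻⁵ e-value
is database-size-scaled and not transferable; α = 0.005 with an add-one
permutation p keeps the null pass rate at or below 0.5 % by
construction.  Note the attainable minimum p is 1/(n_perm+1): n_perm
must be at least ⌈1/α⌉ − 1 (199 at the default α) for the criterion to
be passable at all.  Several tests and the acceptance benchmark's
calibration stage therefore run at n_perm = 199, the smallest passable
setting, which leaves the accept/reject boundary unchanged (only zero
exceedances pass) while keeping runtimes modest.

Permutation streams are seeded per candidate from (run seed, CRC32 of
the candidate id), so adding or removing candidates never changes
another candidate's p-value.

### Criterion 3 — copper-site conservation

The annotated T1/T2/T3a/T3b positions of the assigned reference are
transferred onto the candidate through their global alignment.
Conservation is exact set membership: the aligned candidate residue must
belong to the site's allowed set (e.g. {H} for a T1 histidine, {M,L,F}
for the variable T1 axial ligand).  This is the strictest defensible
reading of "preservation of the amino-acid sequence" of a ligand site;
biochemical tolerance is expressed as data (multi-letter allowed sets in
the reference table), not as a similarity score.  Two fail-closed rules:
an `X` never demonstrates conservation, and a reference position that
lands in a gap is UNMAPPED and fails (a gapped-out ligand cannot bind
copper).  The criterion passes only when all four labels are annotated
on the reference and every annotated position is conserved.

### Criterion 4 — co-clade placement

Distances are Poisson-corrected p-distances from global alignments,
d = −ln(1 − p), with p the fraction of non-identical residue-residue
columns (gap columns excluded); p = 1 maps to a saturation cap of 10.0.
One neighbor-joining tree per run holds all references plus every
candidate that survived criteria 1–3 (candidate leaves are prefixed
`Q|` to avoid label collisions).  Neighbor joining is the in-repo
Saitou–Nei algorithm with deterministic tie-breaking (minimum Q, ties to
the lexicographically smallest node-key pair, where an internal node's
key is the smallest leaf label beneath it) and the standard
negative-branch fix (clamp to 0, shift the deficit to the sibling).  The
tree is rooted at the midpoint of the edge separating the OUTGROUP
leaves (which must be monophyletic — a hard error otherwise).

The clade criterion is formalized as: the leaf set of the most recent
common ancestor of {candidate, assigned reference} must contain no
NEGATIVE reference.  Adding negatives outside that clade can never flip
a pass to a fail.

Distance-NJ stands in for maximum-likelihood tree building with rate
heterogeneity and for the MSA + column-trimming stage: the clade
criterion needs topology, not branch-length inference, and NJ is
provably consistent on additive distances (verified in the tests both
exhaustively at 5 leaves and on random additive matrices).  There is no
bootstrap; clade calls are point estimates.  Because candidates share
one tree, removing a candidate can in principle change another's
criterion-4 outcome through tree composition; criteria 1–3 are per-candidate
and provably unaffected.

## The synthetic generator

`SynthSpec`/`generate` build the benchmark family: an ancestor of 300
residues drawn from BLOSUM62 background frequencies with 10 planted
ligand positions (T1×4 with letters H/C/H/M, and H pairs for T2, T3a,
T3b), pairwise at least 5 residues apart.  Substitutions draw from the
BLOSUM62-conditional distribution P(b|a) ∝ f_b·2^(s(a,b)/2), so identity
decays the way it does between real homologs.  From the ancestor:

- 3 POSITIVE references (labelled *moxA*, *mcoA*, *mnxG* with their
  literature locus ids as stand-in labels; sequences are synthetic) at
  substitution rate 0.1, ligand positions frozen;
- 2 NEGATIVE references at rate 0.4 with all ligand positions mutated to
  alanine; 1 OUTGROUP of pure background;
- candidate classes: positives (rate 0.2, sites frozen), site-ablated
  decoys (positives with every ligand set to alanine — alanine is in no
  allowed set, so they can never pass criterion 3), distant homologs
  (rate 0.8, sites free), and composition-matched shuffles of positives.
- bins: round-robin assignment of candidates to MAG labels; the truth
  table marks exactly the positives as expected passes.

Everything is a pure function of the seed; identical specs produce
byte-identical files.

**A quantitative limitation worth knowing.**  One round of Bernoulli(rate)
substitution with BLOSUM62-conditional draws keeps each position with
probability 1 − rate·(1 − m_a), where m_a ≈ 0.34 is the mean
self-substitution mass.  Expected identity therefore bottoms out near
46 % even at rate 0.8 — the "distant" decoys are *not* below the 30 %
homology cut (their best local hits sit near 45–50 % identity), and
composition-matched shuffles of 300-residue sequences also routinely
show short HSPs above 30 %.  This mirrors real screening: an identity
threshold alone does not separate decoys from targets, and the decoy
classes are rejected where they should be — shuffles by the permutation
null, ablated and distant homologs by the copper-site check.  The
end-to-end benchmark asserts exactly that, not a sub-30 % identity for
distant decoys.

What the generator does not emulate: indels between homologs (positives
are substitution-only), domain architecture variation, compositional
bias of real proteomes, fragmented gene calls at contig edges, and
multi-family reference sets.  Passing the benchmark shows the pipeline's
logic and numerics are sound on data matching its assumptions; it is not
evidence about sensitivity on real MAGs.

## Numerical and interface choices

- Report floats are fixed-format (identity %.2f, p-values %.6g, branch
  lengths %.6f), and rows sort by candidate id, so equal runs are
  byte-identical.
- The benchmark and acceptance run use 25 candidates per class over 10
  MAGs with n_perm = 999 for the screen proper and n_perm = 199 for the
  200-candidate null-calibration stage; these sizes keep the whole
  verification suite at a few minutes on one CPU while every rate they
  measure (sensitivity, false-positive counts, null pass rate) is
  computed, not assumed.
- Input validation is strict and early: duplicate FASTA ids, internal
  stop codons, non-amino-acid letters, malformed or out-of-range site
  annotations, conflicting bin assignments, and an ill-composed
  reference database are all hard errors before any computation.
- The AHP (animal heme peroxidase) Mn-oxidase family is representable in
  the reference table but the screen path is MCO-specific; nucleotide
  input and gene calling are out of scope (the pipeline consumes
  predicted proteins).
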