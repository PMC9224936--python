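"""Criterion 2 — domain compatibility via a reference-derived PSSM.

A position-specific scoring profile is built from the POSITIVE reference
sequences (anchored on the longest one), and each candidate is scored by
summing per-column log-odds along its global alignment to the anchor.
Significance comes from a composition-preserving permutation null: the
candidate's residues are shuffled and re-scored, and the empirical
p-value uses the standard add-one estimator.  This replaces a
profile-HMM search against an external domain database with a
self-contained test of compatibility with the packaged reference family.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

from .align import AA20, BLOSUM62_BACKGROUND, ScoringScheme, global_align
from .seq_io import ProteinRecord, ReferenceGene, Role

_AA_INDEX = {a: k for k, a in enumerate(AA20)}


@dataclass(frozen=True)
class Profile:
    """Per-column log-odds scores indexed by anchor-sequence coordinates.

    ``positions`` are the 1-based anchor positions retained (columns where
    more than half of the references were gapped are dropped);
    ``scores[c, k]`` is the log-odds of amino acid ``AA20[k]`` at retained
    column ``c``.  ``gap_penalty`` is the fixed score contributed by each
    gap column of a candidate's alignment to the anchor.
    """

    anchor_ref: str
    anchor_residues: str
    positions: tuple[int, ...]
    scores: np.ndarray
    background: np.ndarray
    gap_penalty: float = -1.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile scores must be finite")
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be strictly positive")


def build_profile(refs: list[ReferenceGene], pseudocount: float = 1.0,
                  scheme: ScoringScheme | None = None,
                  gap_penalty: float = -1.0) -> Profile:
    """Build the family PSSM from POSITIVE references of one family.

    Each reference is globally aligned to the anchor (the longest
    reference; ties broken by lexicographic ref_id) and residue-residue
    columns accumulate letter counts.  The log-odds score of letter ``a``
    at a column with count ``n_a`` over ``N`` observations is

        log( ((n_a + pc * f_a) / (N + pc)) / f_a )

    with ``f_a`` the BLOSUM62 background frequency and ``pc`` the
    pseudocount mass; as ``pc`` grows all scores shrink to 0.
    """
    positives = [r for r in refs if r.role is Role.POSITIVE]
    if len(positives) < 2:
        raise ValueError("build_profile requires at least 2 POSITIVE references")
    families = {r.family for r in positives}
    if len(families) != 1:
        raise ValueError(f"references span multiple families: {families}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if scheme is None:
        scheme = ScoringScheme()

    # anchor: longest reference, ties to lexicographically smallest ref_id
    max_len = max(len(r.residues) for r in positives)
    anchor = min((r for r in positives if len(r.residues) == max_len),
                 key=lambda r: r.ref_id)

    L = len(anchor.residues)
    counts = np.zeros((L, 20))
    present = np.zeros(L, dtype=int)      # references with a residue here
    for ref in positives:
        if ref.ref_id == anchor.ref_id:
            mapped = {p: anchor.residues[p - 1] for p in range(1, L + 1)}
        else:
            aln = global_align(ref.as_protein(), anchor.as_protein(), scheme)
            mapped = {j: ref.residues[i - 1]
                      for i, j in aln.pairs if i is not None and j is not None}
        for apos, letter in mapped.items():
            present[apos - 1] += 1
            k = _AA_INDEX.get(letter)
            if k is not None:             # 'X' observations carry no count
                counts[apos - 1, k] += 1

    n_refs = len(positives)
    keep = present > n_refs / 2.0         # drop majority-gap columns
    background = np.array([BLOSUM62_BACKGROUND[a] for a in AA20])
    positions = tuple(int(p) for p in np.nonzero(keep)[0] + 1)
    kept_counts = counts[keep]
    totals = kept_counts.sum(axis=1, keepdims=True)
    freq = (kept_counts + pseudocount * background) / (totals + pseudocount)
    scores = np.log(freq / background)
    return Profile(anchor_ref=anchor.ref_id, anchor_residues=anchor.residues,
                   positions=positions, scores=scores, background=background,
                   gap_penalty=gap_penalty)


def profile_score(profile: Profile, candidate: ProteinRecord,
                  scheme: ScoringScheme) -> float:
    """Score a candidate against the profile along its anchor alignment.

    Residue-residue columns at retained anchor positions contribute the
    column log-odds of the candidate letter ('X' contributes 0); every gap
    column contributes ``profile.gap_penalty``; residue-residue columns at
    dropped anchor positions contribute 0.
    """
    anchor = ProteinRecord(id=profile.anchor_ref,
                           residues=profile.anchor_residues)
    aln = global_align(candidate, anchor, scheme)
    return _score_pairs(profile, candidate.residues, aln.pairs)


def _score_pairs(profile: Profile, residues: str, pairs) -> float:
    colmap = {p: c for c, p in enumerate(profile.positions)}
    total = 0.0
    for i, j in pairs:
        if i is None or j is None:
            total += profile.gap_penalty
            continue
        c = colmap.get(j)
        if c is None:
            continue
        k = _AA_INDEX.get(residues[i - 1])
        if k is not None:
            total += float(profile.scores[c, k])
    return total


def candidate_rng(rng_seed: int, candidate_id: str) -> np.random.Generator:
    """Deterministic per-candidate generator, independent of other candidates."""
    tag = zlib.crc32(candidate_id.encode())
    return np.random.default_rng(np.random.SeedSequence([rng_seed, tag]))


def criterion2(profile: Profile, candidate: ProteinRecord,
               scheme: ScoringScheme, n_perm: int = 999,
               alpha: float = 0.005,
               rng: np.random.Generator | int | None = 0
               ) -> tuple[bool, float]:
    """Permutation test of profile compatibility.

    The observed profile score is compared with scores of ``n_perm``
    uniform residue permutations of the candidate (each realigned to the
    anchor); ``p = (1 + #{shuffled >= observed}) / (1 + n_perm)``.
    Passes iff ``p <= alpha``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    observed = profile_score(profile, candidate, scheme)
    letters = np.array(list(candidate.residues))
    exceed = 0
    for _ in range(n_perm):
        perm = "".join(letters[rng.permutation(len(letters))])
        shuffled = ProteinRecord(id=candidate.id, residues=perm)
        if profile_score(profile, shuffled, scheme) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return p <= alpha, p


def max_achievable_score(profile: Profile) -> float:
    """Upper bound: best letter at every retained column, no gaps."""
    return float(profile.scores.max(axis=1).sum())
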