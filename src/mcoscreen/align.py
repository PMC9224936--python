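"""Pairwise protein alignment kernels and the criterion-1 homology filter.

The screen operationalizes "homology with known Mn-oxidizing genes" as the
percent identity of the best affine-gap Smith-Waterman alignment against
each POSITIVE reference (BLOSUM62, gap open 11 / extend 1 — BLASTP protein
defaults).  Needleman-Wunsch global alignment with penalized end gaps
provides the residue-coordinate mapping used downstream for copper-site
transfer and distance estimation.  The dynamic programming itself is
delegated to Bio.Align.PairwiseAligner; this module fixes the scoring
conventions, the coordinate bookkeeping, and the identity measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import ProteinRecord, ReferenceGene, Role

# Marginal amino-acid frequencies of the BLOSUM62 target distribution
# (Henikoff & Henikoff block counts); used as the PSSM background and as
# the synthetic generator's residue pool.  Normalized on import.
BLOSUM62_BACKGROUND: dict[str, float] = {
    "A": 0.0742, "R": 0.0516, "N": 0.0446, "D": 0.0536, "C": 0.0246,
    "Q": 0.0343, "E": 0.0543, "G": 0.0741, "H": 0.0262, "I": 0.0679,
    "L": 0.0989, "K": 0.0582, "M": 0.0248, "F": 0.0473, "P": 0.0387,
    "S": 0.0572, "T": 0.0525, "W": 0.0132, "Y": 0.0322, "V": 0.0730,
}
_tot = sum(BLOSUM62_BACKGROUND.values())
BLOSUM62_BACKGROUND = {a: f / _tot for a, f in BLOSUM62_BACKGROUND.items()}

AA20 = "ARNDCQEGHILKMFPSTWYV"


class Mode(str, Enum):
    LOCAL = "LOCAL"
    GLOBAL = "GLOBAL"


def load_matrix(path: str | Path | None = None):
    """Load a substitution matrix in NCBI text format.

    With no argument, loads the packaged BLOSUM62 table and overrides the
    ``X`` row/column to 0 so an unknown residue neither rewards nor
    penalizes any pairing.
    """
    if path is None:
        ref = resources.files("mcoscreen.data") / "BLOSUM62"
        with resources.as_file(ref) as p:
            mat = substitution_matrices.read(str(p))
    else:
        mat = substitution_matrices.read(str(path))
    if "X" in mat.alphabet:
        for a in mat.alphabet:
            mat["X", a] = 0.0
            mat[a, "X"] = 0.0
    return mat


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap penalties (both nonnegative)."""

    matrix: object = None       # Bio.Align.substitution_matrices.Array
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.matrix is None:
            self.matrix = load_matrix()
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        m = np.asarray(self.matrix)
        if not np.allclose(m, m.T):
            raise ValueError("substitution matrix must be symmetric")


def default_scheme() -> ScoringScheme:
    return ScoringScheme()


@dataclass(frozen=True)
class AlignmentResult:
    """A scored pairwise alignment with its residue-coordinate mapping.

    ``pairs`` lists aligned columns in order: ``(i, j)`` residue-residue,
    ``(i, None)`` query residue over a gap (deletion in subject),
    ``(None, j)`` subject residue over a gap, with 1-based coordinates.
    ``identity_pct`` uses the gap-inclusive denominator (BLAST convention):
    100 x matched columns / total columns.
    """

    score: float
    mode: Mode
    pairs: tuple[tuple[int | None, int | None], ...]
    identity_pct: float
    n_matches: int = 0
    n_residue_columns: int = 0

    def percent_identity(self, include_gap_columns: bool = True) -> float:
        """Identity with either denominator convention."""
        denom = len(self.pairs) if include_gap_columns else self.n_residue_columns
        if denom == 0:
            return 0.0
        return 100.0 * self.n_matches / denom


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(scheme: ScoringScheme, mode: Mode) -> Align.PairwiseAligner:
    key = (id(scheme.matrix), scheme.gap_open, scheme.gap_extend, mode)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = scheme.matrix
        # affine cost: gap of length k costs open + k*extend
        aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        aligner.extend_gap_score = -scheme.gap_extend
        aligner.mode = "local" if mode is Mode.LOCAL else "global"
        _ALIGNER_CACHE[key] = aligner
    return aligner


def _pairs_from_alignment(aln, qlen: int, slen: int, mode: Mode,
                          qseq: str, sseq: str):
    """Convert a Biopython alignment into ordered coordinate pairs."""
    qblocks, sblocks = aln.aligned
    pairs: list[tuple[int | None, int | None]] = []
    if len(qblocks) == 0:
        return tuple(pairs), 0, 0
    if mode is Mode.GLOBAL:
        ci, cj = 0, 0
        end_i, end_j = qlen, slen
    else:
        ci, cj = int(qblocks[0][0]), int(sblocks[0][0])
        end_i, end_j = int(qblocks[-1][1]), int(sblocks[-1][1])
    n_match = 0
    n_rr = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        while ci < qs:                       # subject gap (deletion)
            pairs.append((ci + 1, None))
            ci += 1
        while cj < ss:                       # query gap (insertion)
            pairs.append((None, cj + 1))
            cj += 1
        for _ in range(qe - qs):
            pairs.append((ci + 1, cj + 1))
            if qseq[ci] == sseq[cj]:
                n_match += 1
            n_rr += 1
            ci += 1
            cj += 1
    while ci < end_i:
        pairs.append((ci + 1, None))
        ci += 1
    while cj < end_j:
        pairs.append((None, cj + 1))
        cj += 1
    return tuple(pairs), n_match, n_rr


def _align(query: ProteinRecord, subject: ProteinRecord,
           scheme: ScoringScheme, mode: Mode) -> AlignmentResult:
    aligner = _aligner(scheme, mode)
    qseq, sseq = query.residues, subject.residues
    score = aligner.score(qseq, sseq)
    if mode is Mode.LOCAL and score <= 0:
        # best local alignment is empty; permitted outcome
        return AlignmentResult(score=0.0, mode=mode, pairs=(),
                               identity_pct=0.0)
    # first alignment in the aligner's canonical order: deterministic
    aln = next(iter(aligner.align(qseq, sseq)))
    pairs, n_match, n_rr = _pairs_from_alignment(
        aln, len(qseq), len(sseq), mode, qseq, sseq)
    ident = 100.0 * n_match / len(pairs) if pairs else 0.0
    return AlignmentResult(score=float(score), mode=mode, pairs=pairs,
                           identity_pct=ident, n_matches=n_match,
                           n_residue_columns=n_rr)


def local_align(query: ProteinRecord, subject: ProteinRecord,
                scheme: ScoringScheme) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment under affine gap costs."""
    return _align(query, subject, scheme, Mode.LOCAL)


def global_align(query: ProteinRecord, subject: ProteinRecord,
                 scheme: ScoringScheme) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment, end gaps penalized."""
    return _align(query, subject, scheme, Mode.GLOBAL)


def criterion1(candidate: ProteinRecord, refs: list[ReferenceGene],
               scheme: ScoringScheme, threshold_pct: float = 30.0
               ) -> tuple[bool, str | None, float]:
    """Homology filter: best-hit local identity strictly above the cut.

    Returns ``(passed, best_ref_id, identity_pct)``.  The best hit is the
    POSITIVE reference maximizing local-alignment percent identity (ties:
    higher score, then lexicographic ref_id); it becomes the candidate's
    assigned known Mn-oxidizing gene for criteria 3-4.  The threshold is a
    strict inequality: identity exactly at the cut fails.
    """
    positives = [r for r in refs if r.role is Role.POSITIVE]
    if not positives:
        raise ValueError("criterion1 requires at least one POSITIVE reference")
    if not 0.0 < threshold_pct < 100.0:
        raise ValueError("threshold_pct must be in (0, 100)")
    best: tuple[float, float, str] | None = None
    best_ident = 0.0
    best_id: str | None = None
    for ref in sorted(positives, key=lambda r: r.ref_id):
        res = local_align(candidate, ref.as_protein(), scheme)
        key = (res.identity_pct, res.score, ref.ref_id)
        if best is None or (key[0], key[1]) > (best[0], best[1]):
            best = key
            best_ident = res.identity_pct
            best_id = ref.ref_id
    passed = best_ident > threshold_pct
    return passed, best_id, best_ident
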