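import numpy as np
import pytest

from oracles import global_score, local_score

from mcoscreen import (CuSite, Family, ProteinRecord, ReferenceGene, Role,
                       criterion1, global_align, load_matrix, local_align)

AA4 = "ACDE"


def subfn(scheme):
    mat = scheme.matrix
    return lambda x, y: float(mat[x, y])


def random_pair(rng, max_len=7, alphabet=AA4):
    la, lb = rng.integers(1, max_len + 1, size=2)
    a = "".join(rng.choice(list(alphabet), size=la))
    b = "".join(rng.choice(list(alphabet), size=lb))
    return a, b


class TestKernels:
    def test_blosum_diagonal_example(self, scheme):
        """Identical 'HCH' sequences align residue-by-residue; the score is
        the sum of the packaged BLOSUM62 diagonal entries."""
        mat = load_matrix()
        expected = mat["H", "H"] * 2 + mat["C", "C"]
        res = local_align(ProteinRecord(id="q", residues="HCH"),
                          ProteinRecord(id="s", residues="HCH"), scheme)
        assert res.score == expected
        assert res.identity_pct == 100.0

    def test_all_negative_block_gives_empty_local(self, scheme):
        res = local_align(ProteinRecord(id="q", residues="AAAA"),
                          ProteinRecord(id="s", residues="GGGG"), scheme)
        assert res.score == 0.0 and res.pairs == ()

    def test_single_deletion_column(self, scheme):
        """'MKH' vs 'MH': every optimal global alignment has exactly one
        deletion column (verified by the enumeration oracle)."""
        res = global_align(ProteinRecord(id="q", residues="MKH"),
                           ProteinRecord(id="s", residues="MH"), scheme)
        assert res.score == global_score("MKH", "MH", subfn(scheme), 11, 1)
        gaps = [(i, j) for i, j in res.pairs if i is None or j is None]
        assert gaps == [(2, None)]

    def test_scores_match_enumeration_oracle(self, scheme):
        """Local and global affine-gap scores equal brute-force enumeration
        over all gapped alignments (short sequences, 4-letter alphabet)."""
        rng = np.random.default_rng(1)
        sub = subfn(scheme)
        for _ in range(40):
            a, b = random_pair(rng)
            q = ProteinRecord(id="q", residues=a)
            s = ProteinRecord(id="s", residues=b)
            assert global_align(q, s, scheme).score == pytest.approx(
                global_score(a, b, sub, 11, 1))
            assert local_align(q, s, scheme).score == pytest.approx(
                local_score(a, b, sub, 11, 1))

    def test_global_symmetry(self, scheme):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = random_pair(rng, alphabet="ACDEFGHIKL")
            q = ProteinRecord(id="q", residues=a)
            s = ProteinRecord(id="s", residues=b)
            fwd = global_align(q, s, scheme)
            rev = global_align(s, q, scheme)
            assert fwd.score == rev.score
            assert fwd.identity_pct == pytest.approx(rev.identity_pct)
            assert {(i, j) for i, j in fwd.pairs} == \
                {(j, i) for i, j in rev.pairs}

    def test_self_identity_is_100(self, scheme):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, _ = random_pair(rng, max_len=30, alphabet="ACDEFGHIKLMNPQRSTVWY")
            q = ProteinRecord(id="q", residues=a)
            assert global_align(q, q, scheme).identity_pct == 100.0

    def test_appending_shared_suffix_monotone(self, scheme):
        """Appending identical residues to both sequences never decreases
        the global match count."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b = random_pair(rng, max_len=10, alphabet="ACDEFGHIKL")
            base = global_align(ProteinRecord(id="q", residues=a),
                                ProteinRecord(id="s", residues=b),
                                scheme).n_matches
            ext = global_align(ProteinRecord(id="q", residues=a + "WWW"),
                               ProteinRecord(id="s", residues=b + "WWW"),
                               scheme).n_matches
            assert ext >= base

    def test_gapless_denominator_option(self, scheme):
        res = global_align(ProteinRecord(id="q", residues="MKH"),
                           ProteinRecord(id="s", residues="MH"), scheme)
        assert res.percent_identity(include_gap_columns=True) == \
            pytest.approx(100 * 2 / 3)
        assert res.percent_identity(include_gap_columns=False) == 100.0


def tiny_positive(ref_id, residues, site_positions):
    """A minimal POSITIVE reference annotating all four labels."""
    labels = ["T1", "T2", "T3a", "T3b"]
    sites = tuple(
        CuSite(label=lab, position=p, allowed=frozenset(residues[p - 1]))
        for lab, p in zip(labels, site_positions))
    return ReferenceGene(ref_id=ref_id, gene_name=ref_id, locus_id="-",
                         family=Family.MCO, role=Role.POSITIVE,
                         residues=residues, sites=sites)


class TestCriterion1:
    # candidate/reference pair engineered so the optimal local alignment is
    # the full-length ungapped diagonal: 3 identities + 7 positive-scoring
    # mismatches (K/R, I/L, F/Y) = exactly 30.0% identity
    REF = tiny_positive("ref30", "WRLYHRLYCR", (1, 5, 9, 10))
    CAND_30 = "WKIFHKIFCK"
    CAND_40 = "WRIFHKIFCK"      # one mismatch converted to a match

    def test_exact_threshold_fails_strictly(self, scheme):
        passed, best, ident = criterion1(
            ProteinRecord(id="c", residues=self.CAND_30), [self.REF],
            scheme, threshold_pct=30.0)
        assert ident == pytest.approx(30.0)
        assert not passed

    def test_just_above_threshold_passes(self, scheme):
        passed, _, ident = criterion1(
            ProteinRecord(id="c", residues=self.CAND_40), [self.REF],
            scheme, threshold_pct=30.0)
        assert ident > 30.0 and passed

    def test_identical_candidate_recovers_reference(self, scheme,
                                                    positive_refs):
        ref = positive_refs[0]
        cand = ProteinRecord(id="c", residues=ref.residues)
        passed, best, ident = criterion1(cand, positive_refs, scheme)
        assert passed and best == ref.ref_id and ident == 100.0

    def test_best_hit_matches_exhaustive_recomputation(self, scheme,
                                                       positive_refs):
        """Best hit of a shuffled reference equals the brute-force argmax
        of local identity over all references."""
        rng = np.random.default_rng(1)
        base = positive_refs[0].residues[:200]
        cand = ProteinRecord(
            id="c", residues="".join(rng.permutation(list(base))))
        _, best, ident = criterion1(cand, positive_refs, scheme)
        scored = []
        for ref in positive_refs:
            res = local_align(cand, ref.as_protein(), scheme)
            scored.append((res.identity_pct, res.score, ref.ref_id))
        top = sorted(scored, key=lambda t: (-t[0], -t[1], t[2]))[0]
        assert ident == pytest.approx(top[0])
        assert best == top[2]

    def test_requires_positive_reference(self, scheme):
        with pytest.raises(ValueError, match="POSITIVE"):
            criterion1(ProteinRecord(id="c", residues="MKH"), [], scheme)
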