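"""Synthetic protein-family generator with known ground truth.

Emulates the statistical structure the screen assumes: an ancestral
multicopper-oxidase-like sequence with annotated T1/T2/T3a/T3b
copper-binding positions, a small reference database derived from it
(three known Mn-oxidizing genes labelled moxA/mcoA/mnxG, two negative
MCOs, one outgroup), and four candidate classes — true homologs evolved
at a tunable substitution rate with ligand positions frozen, site-ablated
decoys, sub-threshold distant homologs, and composition-matched shuffles.

The moxA/mcoA/mnxG names and locus ids (CAJ19378, ABY98562, PputGB1_2447)
are stand-in labels for the field's named Mn-oxidizing reference genes;
all sequences here are synthetic, not the real loci.

Substitutions are drawn from BLOSUM62-conditional frequencies, so
identity decays the way it does between real homologs rather than
uniformly over the alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import AA20, BLOSUM62_BACKGROUND, load_matrix
from .seq_io import (CuSite, Family, ProteinRecord, ReferenceGene, Role,
                     write_bins, write_fasta, write_refdb)

# canonical MCO ligand letters per site label; T1's fourth (axial) position
# tolerates Met/Leu/Phe
_T1_LETTERS = ("H", "C", "H", "M")
_T1_ALLOWED = (frozenset("H"), frozenset("C"), frozenset("H"), frozenset("MLF"))

MIN_SITE_SPACING = 5


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    rng_seed: int = 0
    n_pos: int = 10
    n_ablate: int = 10
    n_far: int = 10
    n_shuffle: int = 10
    sub_rate_pos: float = 0.2      # per-site substitution prob., positives
    sub_rate_far: float = 0.8      # distant (sub-threshold) homologs
    sub_rate_ref: float = 0.1      # POSITIVE references vs the ancestor
    sub_rate_neg: float = 0.4      # NEGATIVE (ablated divergent) references
    n_bins: int = 5
    family_length: int = 300
    n_sites: int = 10

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_ablate", "n_far", "n_shuffle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sub_rate_pos", "sub_rate_far", "sub_rate_ref",
                     "sub_rate_neg"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.n_sites < 7:
            raise ValueError("need n_sites >= 7 to cover all four site labels")
        if self.family_length < self.n_sites * (MIN_SITE_SPACING + 1) + 10:
            raise ValueError("family_length too short for the site layout")


@dataclass
class SynthDataset:
    ancestor: ReferenceGene
    refs: list[ReferenceGene]
    candidates: list[ProteinRecord]
    bins: dict[str, str]
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# Substitution machinery

_BACKGROUND = np.array([BLOSUM62_BACKGROUND[a] for a in AA20])


def _conditional_matrix() -> np.ndarray:
    """P(b | a) from BLOSUM62 half-bit scores: q_ab proportional to
    f_a * f_b * 2^(s_ab / 2)."""
    mat = load_matrix()
    s = np.array([[float(mat[a, b]) for b in AA20] for a in AA20])
    q = _BACKGROUND[:, None] * _BACKGROUND[None, :] * np.power(2.0, s / 2.0)
    return q / q.sum(axis=1, keepdims=True)


_COND = _conditional_matrix()
_AA_IDX = {a: i for i, a in enumerate(AA20)}

#: probability that a BLOSUM62-conditional substitution keeps the letter
SELF_SUBSTITUTION_MASS = {a: float(_COND[i, i]) for i, a in enumerate(AA20)}


def _site_plan(n_sites: int) -> tuple[tuple[str, ...], tuple[str, ...],
                                      tuple[frozenset[str], ...]]:
    labels = ["T1"] * 4
    letters = list(_T1_LETTERS)
    allowed = list(_T1_ALLOWED)
    cycle = ("T2", "T3a", "T3b")
    for k in range(n_sites - 4):
        labels.append(cycle[k % 3])
        letters.append("H")
        allowed.append(frozenset("H"))
    return tuple(labels), tuple(letters), tuple(allowed)


def _sample_positions(rng: np.random.Generator, n: int, length: int
                      ) -> tuple[int, ...]:
    """n distinct 1-based positions, pairwise >= MIN_SITE_SPACING apart,
    away from the sequence ends."""
    lo, hi = MIN_SITE_SPACING, length - MIN_SITE_SPACING
    while True:
        pos = np.sort(rng.choice(np.arange(lo, hi + 1), size=n, replace=False))
        if np.all(np.diff(pos) >= MIN_SITE_SPACING):
            return tuple(int(p) for p in pos)


def make_ancestor(spec: SynthSpec,
                  rng: np.random.Generator | None = None) -> ReferenceGene:
    """Random ancestor drawn from BLOSUM62 background frequencies, with
    the canonical ligand letters planted at the annotated site positions."""
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    labels, letters, allowed = _site_plan(spec.n_sites)
    positions = _sample_positions(rng, spec.n_sites, spec.family_length)
    seq = list(rng.choice(list(AA20), size=spec.family_length, p=_BACKGROUND))
    sites = []
    for lab, letter, allow, pos in zip(labels, letters, allowed, positions):
        seq[pos - 1] = letter
        sites.append(CuSite(label=lab, position=pos, allowed=allow))
    return ReferenceGene(ref_id="ancestor", gene_name="ancestor",
                         locus_id="-", family=Family.MCO, role=Role.POSITIVE,
                         residues="".join(seq), sites=tuple(sites))


def evolve(seq: str, frozen_positions: set[int], rate: float,
           rng: np.random.Generator) -> str:
    """Independently substitute each non-frozen position with probability
    ``rate``, drawing the replacement from the BLOSUM62-conditional
    distribution of the current letter (self-substitution allowed)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    out = list(seq)
    hits = rng.random(len(out)) < rate
    for pos0 in np.nonzero(hits)[0]:
        if (pos0 + 1) in frozen_positions:
            continue
        idx = _AA_IDX.get(out[pos0])
        if idx is None:       # 'X' or nonstandard: draw from background
            out[pos0] = str(rng.choice(list(AA20), p=_BACKGROUND))
        else:
            out[pos0] = str(rng.choice(list(AA20), p=_COND[idx]))
    return "".join(out)


def _ablate(seq: str, positions: tuple[int, ...]) -> str:
    out = list(seq)
    for p in positions:
        out[p - 1] = "A"      # alanine sits in no ligand allowed-set
    return "".join(out)


# ---------------------------------------------------------------------------
# Dataset assembly

_REF_PLAN = (("REF_moxA", "moxA", "CAJ19378"),
             ("REF_mcoA", "mcoA", "ABY98562"),
             ("REF_mnxG", "mnxG", "PputGB1_2447"))


def generate(spec: SynthSpec, out_dir: str | Path | None = None
             ) -> SynthDataset:
    """Build the dataset; optionally write candidates.faa, refdb.tsv,
    bins.tsv and truth.tsv to ``out_dir``.  Deterministic: identical
    specs produce byte-identical files."""
    rng = np.random.default_rng(spec.rng_seed)
    ancestor = make_ancestor(spec, rng)
    positions = tuple(s.position for s in ancestor.sites)
    frozen = set(positions)

    refs: list[ReferenceGene] = []
    for ref_id, gene, locus in _REF_PLAN:
        seq = evolve(ancestor.residues, frozen, spec.sub_rate_ref, rng)
        refs.append(ReferenceGene(ref_id=ref_id, gene_name=gene,
                                  locus_id=locus, family=Family.MCO,
                                  role=Role.POSITIVE, residues=seq,
                                  sites=ancestor.sites))
    for k in range(2):
        seq = _ablate(evolve(ancestor.residues, set(), spec.sub_rate_neg, rng),
                      positions)
        refs.append(ReferenceGene(ref_id=f"REF_neg{k + 1}",
                                  gene_name=f"mco_neg{k + 1}", locus_id="-",
                                  family=Family.MCO, role=Role.NEGATIVE,
                                  residues=seq, sites=ancestor.sites))
    out_seq = "".join(rng.choice(list(AA20), size=spec.family_length,
                                 p=_BACKGROUND))
    refs.append(ReferenceGene(ref_id="REF_out", gene_name="outgroup",
                              locus_id="-", family=Family.MCO,
                              role=Role.OUTGROUP, residues=out_seq))

    candidates: list[ProteinRecord] = []
    rows = []

    def add(cid: str, residues: str, klass: str, expected: bool) -> None:
        candidates.append(ProteinRecord(id=cid, residues=residues,
                                        description=klass))
        rows.append({"candidate_id": cid, "class": klass,
                     "expected_call": expected})

    for k in range(spec.n_pos):
        add(f"POS_{k:03d}",
            evolve(ancestor.residues, frozen, spec.sub_rate_pos, rng),
            "positive", True)
    for k in range(spec.n_ablate):
        seq = evolve(ancestor.residues, frozen, spec.sub_rate_pos, rng)
        add(f"ABL_{k:03d}", _ablate(seq, positions), "ablated", False)
    for k in range(spec.n_far):
        add(f"FAR_{k:03d}",
            evolve(ancestor.residues, set(), spec.sub_rate_far, rng),
            "far", False)
    for k in range(spec.n_shuffle):
        seq = evolve(ancestor.residues, frozen, spec.sub_rate_pos, rng)
        perm = rng.permutation(len(seq))
        add(f"SHUF_{k:03d}", "".join(seq[i] for i in perm), "shuffle", False)

    bins = {c.id: f"MAG{(i % spec.n_bins) + 1:02d}"
            for i, c in enumerate(candidates)}
    truth = pd.DataFrame(rows, columns=["candidate_id", "class",
                                        "expected_call"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(candidates, out / "candidates.faa")
        write_refdb(refs, out / "refdb.tsv")
        write_bins(bins, out / "bins.tsv")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    return SynthDataset(ancestor=ancestor, refs=refs, candidates=candidates,
                        bins=bins, truth=truth)
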