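"""Criterion 3 — conservation of the four copper-binding sites.

Multicopper oxidases coordinate at least four Cu atoms at the conserved
T1, T2, T3a and T3b centers, each defined by specific ligand residues
(His/Cys, with a variable axial position at T1).  The annotated ligand
positions of the assigned reference are transferred onto the candidate
through their global alignment; a candidate conserves a site when the
aligned residue falls inside that site's allowed set.  A reference
position that lands in a gap (no aligned candidate residue) is UNMAPPED
and fails closed — a gapped-out copper ligand cannot bind copper.  An
unknown residue 'X' never demonstrates conservation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import ScoringScheme, global_align
from .seq_io import SITE_LABELS, ProteinRecord, ReferenceGene


@dataclass(frozen=True)
class SiteCheck:
    """Outcome of transferring one annotated Cu-site onto a candidate."""

    label: str
    ref_position: int
    ref_letter: str
    allowed: frozenset[str]
    candidate_position: int | None    # None = UNMAPPED
    observed: str | None
    conserved: bool

    def __post_init__(self) -> None:
        if self.conserved and (self.candidate_position is None
                               or self.observed not in self.allowed):
            raise ValueError("conserved site must be mapped with an allowed residue")


def map_sites(candidate: ProteinRecord, ref: ReferenceGene,
              scheme: ScoringScheme) -> list[SiteCheck]:
    """Transfer every annotated site of ``ref`` onto ``candidate``."""
    if not ref.sites:
        raise ValueError(f"reference {ref.ref_id!r} has no annotated sites")
    aln = global_align(candidate, ref.as_protein(), scheme)
    # candidate position aligned to each reference position
    ref_to_cand = {j: i for i, j in aln.pairs
                   if i is not None and j is not None}
    checks = []
    for site in ref.sites:
        cand_pos = ref_to_cand.get(site.position)
        if cand_pos is None:
            checks.append(SiteCheck(
                label=site.label, ref_position=site.position,
                ref_letter=ref.residues[site.position - 1],
                allowed=site.allowed, candidate_position=None,
                observed=None, conserved=False))
        else:
            observed = candidate.residues[cand_pos - 1]
            checks.append(SiteCheck(
                label=site.label, ref_position=site.position,
                ref_letter=ref.residues[site.position - 1],
                allowed=site.allowed, candidate_position=cand_pos,
                observed=observed,
                conserved=observed in site.allowed))
    return checks


def criterion3(candidate: ProteinRecord, ref: ReferenceGene,
               scheme: ScoringScheme) -> tuple[bool, list[SiteCheck]]:
    """All four site labels must be annotated and every position conserved.

    A label missing from the reference annotation fails closed: passing
    requires T1, T2, T3a and T3b all present and all their positions
    conserved.
    """
    checks = map_sites(candidate, ref, scheme)
    labels = {c.label for c in checks}
    all_labels = all(lab in labels for lab in SITE_LABELS)
    passed = all_labels and all(c.conserved for c in checks)
    return passed, checks
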