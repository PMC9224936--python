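"""Reading and writing the screen's external representations.

Protein FASTA (candidate proteomes from MAGs), the tab-separated
reference-gene table with annotated copper-binding sites, the
candidate-to-bin membership table, and the screen report / per-bin
summary files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: letters accepted in input sequences ('X' = unknown residue)
VALID_AA = STANDARD_AA | {"X"}

SITE_LABELS = ("T1", "T2", "T3a", "T3b")

UNBINNED = "UNBINNED"


class Family(str, Enum):
    """Mn-oxidase gene family; the screen itself handles MCOs."""

    MCO = "MCO"
    AHP = "AHP"


class Role(str, Enum):
    POSITIVE = "POSITIVE"   # known Mn-oxidizing gene
    NEGATIVE = "NEGATIVE"   # MCO without Mn-oxidation evidence
    OUTGROUP = "OUTGROUP"


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate or reference amino-acid sequence.

    Parameters
    ----------
    id : str
        Unique identifier (no whitespace).
    residues : str
        Uppercase sequence over the 20 standard letters plus ``X``.
    description : str
        Free-text header remainder.
    bin_id : str, optional
        MAG membership label; ``None`` means unbinned.
    """

    id: str
    residues: str
    description: str = ""
    bin_id: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for pos, c in enumerate(self.residues, start=1):
            if c not in VALID_AA:
                raise ValueError(
                    f"record {self.id!r}: invalid residue {c!r} at position {pos}"
                )


@dataclass(frozen=True)
class CuSite:
    """One annotated copper-binding position on a reference sequence."""

    label: str            # one of T1, T2, T3a, T3b
    position: int         # 1-based index into the reference sequence
    allowed: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.label not in SITE_LABELS:
            raise ValueError(f"unknown site label {self.label!r}")
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        if not self.allowed or not set(self.allowed) <= STANDARD_AA:
            raise ValueError(
                f"allowed set {set(self.allowed)!r} must be a non-empty subset "
                "of the 20 standard letters"
            )


@dataclass(frozen=True)
class ReferenceGene:
    """A known Mn-oxidizing gene, negative MCO, or outgroup sequence."""

    ref_id: str
    gene_name: str
    locus_id: str
    family: Family
    role: Role
    residues: str
    sites: tuple[CuSite, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.residues)
        for s in self.sites:
            if s.position > n:
                raise ValueError(
                    f"ref {self.ref_id!r}: site {s.label} position {s.position} "
                    f"out of range for sequence of length {n}"
                )
        if self.role is Role.POSITIVE and self.family is Family.MCO:
            present = {s.label for s in self.sites}
            missing = [lab for lab in SITE_LABELS if lab not in present]
            if missing:
                raise ValueError(
                    f"ref {self.ref_id!r}: POSITIVE MCO must annotate all four "
                    f"copper-binding sites; missing {missing}"
                )
        if not self.sites and self.role is not Role.OUTGROUP:
            raise ValueError(
                f"ref {self.ref_id!r}: sites may be empty only for OUTGROUP"
            )

    def as_protein(self) -> ProteinRecord:
        return ProteinRecord(id=self.ref_id, residues=self.residues,
                             description=self.gene_name)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased; a single trailing ``*`` stop symbol is
    stripped.  Duplicate ids, empty sequences, internal stops and
    non-amino-acid characters are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise ValueError(
                f"{path}: record {rec.id!r} has an internal stop codon "
                f"at position {seq.index('*') + 1}"
            )
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, residues=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped protein FASTA."""
    seqs = []
    for r in records:
        seqs.append(SeqRecord(Seq(r.residues), id=r.id,
                              description=r.description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Reference-gene table
#
# Tab-separated columns: ref_id, gene_name, locus_id, family, role, sites,
# sequence.  Sites serialize as semicolon-separated "LABEL:POS=ALLOWED"
# entries, e.g. "T1:452=C;T1:457=H;T1:462=MLF".

REFDB_COLUMNS = ("ref_id", "gene_name", "locus_id", "family", "role",
                 "sites", "sequence")


def _parse_sites(text: str, lineno: int) -> tuple[CuSite, ...]:
    text = text.strip()
    if not text or text == "-":
        return ()
    sites = []
    for entry in text.split(";"):
        entry = entry.strip()
        try:
            label, rest = entry.split(":", 1)
            pos_s, allowed = rest.split("=", 1)
            site = CuSite(label=label, position=int(pos_s),
                          allowed=frozenset(allowed))
        except ValueError as exc:
            raise ValueError(
                f"line {lineno}: malformed site entry {entry!r}: {exc}"
            ) from exc
        sites.append(site)
    return tuple(sites)


def format_sites(sites: Sequence[CuSite]) -> str:
    if not sites:
        return "-"
    return ";".join(
        f"{s.label}:{s.position}={''.join(sorted(s.allowed))}" for s in sites
    )


def read_refdb(path: str | Path) -> list[ReferenceGene]:
    """Parse the tab-separated reference-gene table.

    Unknown extra columns are ignored with a warning; malformed rows are
    hard errors reported with their line number.
    """
    refs: list[ReferenceGene] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        missing = [c for c in REFDB_COLUMNS if c not in idx]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        extra = [c for c in header if c not in REFDB_COLUMNS]
        if extra:
            warnings.warn(f"{path}: ignoring unknown columns {extra}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            row = {c: fields[idx[c]] for c in REFDB_COLUMNS}
            try:
                family = Family(row["family"])
                role = Role(row["role"])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            try:
                ref = ReferenceGene(
                    ref_id=row["ref_id"],
                    gene_name=row["gene_name"],
                    locus_id=row["locus_id"],
                    family=family,
                    role=role,
                    residues=row["sequence"].upper(),
                    sites=_parse_sites(row["sites"], lineno),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            refs.append(ref)
    ids = [r.ref_id for r in refs]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate ref_id {dup}")
    return refs


def write_refdb(refs: Iterable[ReferenceGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REFDB_COLUMNS) + "\n")
        for r in refs:
            fh.write("\t".join([
                r.ref_id, r.gene_name, r.locus_id, r.family.value,
                r.role.value, format_sites(r.sites), r.residues,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Bin membership

def read_bins(path: str | Path) -> dict[str, str]:
    """Read the two-column candidate-id → bin-id table.

    Lines starting with ``#`` are ignored.  A candidate listed twice with
    different bins is a hard error; ids absent from the table are treated
    downstream as bin ``UNBINNED``.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            cid, bin_id = parts[0].strip(), parts[1].strip()
            if cid in mapping and mapping[cid] != bin_id:
                raise ValueError(
                    f"{path}: line {lineno}: candidate {cid!r} assigned to both "
                    f"{mapping[cid]!r} and {bin_id!r}"
                )
            mapping[cid] = bin_id
    return mapping


def write_bins(mapping: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#candidate_id\tbin_id\n")
        for cid in mapping:
            fh.write(f"{cid}\t{mapping[cid]}\n")


# ---------------------------------------------------------------------------
# Screen report
#
# write_report accepts any iterable of per-candidate result objects carrying
# the attributes written below (the screen module's ScreenResult).  Keeping
# the writer duck-typed avoids a circular import with the orchestrator.

REPORT_COLUMNS = ("candidate_id", "bin_id", "best_ref_id", "best_gene_name",
                  "identity_pct", "c1_pass", "c2_pass", "c2_pvalue",
                  "c3_pass", "c3_sites", "c4_pass", "final_call")

SUMMARY_COLUMNS = ("bin_id", "n_candidates", "n_pass", "pass_gene_names")

NOT_EVALUATED = "NA"


def _flag(value: bool | None) -> str:
    return NOT_EVALUATED if value is None else ("true" if value else "false")


def format_site_checks(checks) -> str:
    """Serialize SiteChecks as ``T1:H102=H(ok);T1:C452=A(miss);...``."""
    if checks is None:
        return NOT_EVALUATED
    parts = []
    for c in checks:
        obs = c.observed if c.observed is not None else "-"
        status = "ok" if c.conserved else (
            "miss" if c.candidate_position is not None else "unmapped")
        parts.append(f"{c.label}:{c.ref_letter}{c.ref_position}={obs}({status})")
    return ";".join(parts)


def write_report(results, report_path: str | Path,
                 summary_path: str | Path) -> None:
    """Write the per-candidate report and the per-bin summary.

    Rows are ordered by candidate id so identical runs produce
    byte-identical files.
    """
    results = sorted(results, key=lambda r: r.candidate_id)
    with open(report_path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in results:
            fh.write("\t".join([
                r.candidate_id,
                r.bin_id,
                r.best_ref_id if r.best_ref_id is not None else NOT_EVALUATED,
                r.best_gene_name if r.best_gene_name is not None else NOT_EVALUATED,
                f"{r.identity_pct:.2f}" if r.identity_pct is not None else NOT_EVALUATED,
                _flag(r.c1_pass),
                _flag(r.c2_pass),
                f"{r.c2_pvalue:.6g}" if r.c2_pvalue is not None else NOT_EVALUATED,
                _flag(r.c3_pass),
                format_site_checks(r.site_checks),
                _flag(r.c4_pass),
                "true" if r.final_call else "false",
            ]) + "\n")

    bins: dict[str, list] = {}
    for r in results:
        bins.setdefault(r.bin_id, []).append(r)
    with open(summary_path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for bin_id in sorted(bins):
            members = bins[bin_id]
            passers = [r for r in members if r.final_call]
            genes = sorted({r.best_gene_name for r in passers})
            fh.write("\t".join([
                bin_id, str(len(members)), str(len(passers)),
                ",".join(genes) if genes else "-",
            ]) + "\n")
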