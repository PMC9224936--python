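"""Orchestrate the four-criterion Mn-oxidizing gene screen.

Each candidate is evaluated in order — (1) best-hit identity above the
homology cut, (2) PSSM permutation test of domain compatibility,
(3) conservation of the four copper-binding sites of the assigned
reference, (4) co-clade placement with that reference in a
neighbor-joining tree rooted on the outgroup — short-circuiting on the
first failure.  A single tree per run holds all references plus every
candidate that reached criterion 4.  Results roll up per MAG: a bin
possesses a putative Mn-oxidizing gene iff at least one of its
candidates passes all criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
from skbio import TreeNode

from . import phylo
from .align import ScoringScheme, criterion1
from .cusite import SiteCheck, criterion3
from .domain_profile import Profile, build_profile, candidate_rng, criterion2
from .seq_io import UNBINNED, ProteinRecord, ReferenceGene, Role

#: prefix distinguishing candidate leaves from reference leaves in the tree
QUERY_PREFIX = "Q|"


@dataclass
class ScreenConfig:
    """Thresholds and knobs of the screen.

    ``identity_threshold_pct`` is the strict lower bound of criterion 1
    (candidates must exceed it); ``alpha``/``n_perm`` parameterize the
    criterion-2 permutation test; ``rng_seed`` drives every stochastic
    component.  Setting ``run_criterion2`` off skips the domain test,
    which can only enlarge the pass set.
    """

    identity_threshold_pct: float = 30.0
    alpha: float = 0.005
    n_perm: int = 999
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    rng_seed: int = 0
    run_criterion2: bool = True
    pseudocount: float = 1.0
    profile_gap_penalty: float = -1.0
    distance_cap: float = phylo.SATURATION_CAP

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold_pct < 100.0:
            raise ValueError("identity_threshold_pct must be in (0, 100)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")


@dataclass
class ScreenResult:
    """Per-candidate outcome; ``None`` marks a criterion NOT_EVALUATED."""

    candidate_id: str
    bin_id: str
    best_ref_id: str | None = None
    best_gene_name: str | None = None
    identity_pct: float | None = None
    c1_pass: bool | None = None
    c2_pass: bool | None = None
    c2_pvalue: float | None = None
    c3_pass: bool | None = None
    site_checks: list[SiteCheck] | None = None
    c4_pass: bool | None = None
    clade: frozenset[str] | None = None
    final_call: bool = False


@dataclass
class ScreenRun:
    """Bundle of per-candidate results plus the run's phylogeny."""

    results: list[ScreenResult]
    tree: TreeNode | None
    profile: Profile | None
    config: ScreenConfig


def _validate_refdb(refdb: list[ReferenceGene]) -> None:
    n_pos = sum(r.role is Role.POSITIVE for r in refdb)
    n_neg = sum(r.role is Role.NEGATIVE for r in refdb)
    n_out = sum(r.role is Role.OUTGROUP for r in refdb)
    if n_pos < 2 or n_neg < 1 or n_out < 1:
        raise ValueError(
            "reference database must contain >= 2 POSITIVE, >= 1 NEGATIVE "
            f"and >= 1 OUTGROUP entries (got {n_pos}/{n_neg}/{n_out})")


def run_screen(candidates: list[ProteinRecord],
               refdb: list[ReferenceGene],
               bins: dict[str, str] | None = None,
               config: ScreenConfig | None = None) -> ScreenRun:
    """Evaluate criteria 1-4 for every candidate.

    Criteria are evaluated in order with short-circuiting; candidates
    surviving criteria 1-3 are placed, together with all references, in
    one neighbor-joining tree rooted on the OUTGROUP references, and
    criterion 4 is read off that tree.  Deterministic given
    ``config.rng_seed``: each candidate's permutation stream is derived
    from the seed and its own id, so adding or removing candidates never
    perturbs another candidate's criteria 1-3.
    """
    config = config or ScreenConfig()
    bins = bins or {}
    _validate_refdb(refdb)
    ids = [c.id for c in candidates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate candidate ids")

    positives = [r for r in refdb if r.role is Role.POSITIVE]
    by_id = {r.ref_id: r for r in refdb}
    profile = None
    if config.run_criterion2:
        profile = build_profile(positives, pseudocount=config.pseudocount,
                                scheme=config.scheme,
                                gap_penalty=config.profile_gap_penalty)

    results: list[ScreenResult] = []
    survivors: list[ScreenResult] = []
    for cand in sorted(candidates, key=lambda c: c.id):
        res = ScreenResult(candidate_id=cand.id,
                           bin_id=bins.get(cand.id, UNBINNED))
        results.append(res)

        passed1, best_id, ident = criterion1(
            cand, positives, config.scheme, config.identity_threshold_pct)
        res.c1_pass = passed1
        res.best_ref_id = best_id
        res.best_gene_name = by_id[best_id].gene_name if best_id else None
        res.identity_pct = ident
        if not passed1:
            continue

        if config.run_criterion2:
            rng = candidate_rng(config.rng_seed, cand.id)
            passed2, pvalue = criterion2(
                profile, cand, config.scheme, n_perm=config.n_perm,
                alpha=config.alpha, rng=rng)
            res.c2_pass = passed2
            res.c2_pvalue = pvalue
            if not passed2:
                continue

        passed3, checks = criterion3(cand, by_id[best_id], config.scheme)
        res.c3_pass = passed3
        res.site_checks = checks
        if not passed3:
            continue
        survivors.append(res)

    tree = _build_tree(candidates, refdb, survivors, config)
    if survivors:
        negative_ids = {r.ref_id for r in refdb if r.role is Role.NEGATIVE}
        for res in survivors:
            passed4, clade = phylo.criterion4(
                QUERY_PREFIX + res.candidate_id, res.best_ref_id, tree,
                negative_ids)
            res.c4_pass = passed4
            res.clade = clade
            res.final_call = bool(
                res.c1_pass and (res.c2_pass or not config.run_criterion2)
                and res.c3_pass and res.c4_pass)
    return ScreenRun(results=results, tree=tree, profile=profile,
                     config=config)


def _build_tree(candidates, refdb, survivors, config) -> TreeNode | None:
    """One tree per run: all references plus criterion-4 candidates."""
    by_id = {c.id: c for c in candidates}
    leaves = [r.as_protein() for r in refdb]
    for res in survivors:
        cand = by_id[res.candidate_id]
        leaves.append(ProteinRecord(id=QUERY_PREFIX + cand.id,
                                    residues=cand.residues))
    if len(leaves) < 3:
        return None
    dm = phylo.distance_matrix(leaves, config.scheme, cap=config.distance_cap)
    tree = phylo.nj_tree(dm)
    outgroup = {r.ref_id for r in refdb if r.role is Role.OUTGROUP}
    return phylo.root_at_outgroup(tree, outgroup)


def summarize_bins(results: list[ScreenResult]) -> pd.DataFrame:
    """Per-MAG rollup: a bin possesses a putative Mn-oxidizing gene iff
    at least one of its candidates passes all criteria."""
    rows = []
    bins: dict[str, list[ScreenResult]] = {}
    for r in results:
        bins.setdefault(r.bin_id, []).append(r)
    for bin_id in sorted(bins):
        members = bins[bin_id]
        passers = [r for r in members if r.final_call]
        rows.append({
            "bin_id": bin_id,
            "n_candidates": len(members),
            "n_pass": len(passers),
            "pass_gene_names": ",".join(
                sorted({r.best_gene_name for r in passers})) or "-",
            "possesses_mn_oxidizing_gene": len(passers) >= 1,
        })
    return pd.DataFrame(
        rows, columns=["bin_id", "n_candidates", "n_pass",
                       "pass_gene_names", "possesses_mn_oxidizing_gene"])
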