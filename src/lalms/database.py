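"""Candidate enumeration: every crosslinked species a peptide set can form.

Crosslink searches are combinatorial: n peptides give (n^2 + n)/2 unordered
pairs (homodimers included), and each pair multiplies further by link type,
donor/acceptor site choice and concurrent-modification state.  This module
enumerates that space exhaustively for a small peptide set, indexes the
result by precursor m/z, and keeps isobaric entries (e.g. lanthionine vs
Cys-derived lysinoalanine) as distinct, cross-referenced records.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from itertools import product
from typing import Sequence

from .chem import (
    ACCEPTOR_RESIDUES,
    DONOR_RESIDUES,
    LINK_TYPES,
    MODIFICATIONS,
    ChemError,
    CrosslinkSpecies,
    PeptideSpec,
    apply_modifications,
    crosslink_mass,
    mz,
    peptide_mass,
)

__all__ = [
    "SpeciesRecord",
    "CandidateDatabase",
    "pair_count",
    "enumerate_modified_variants",
    "enumerate_species",
    "query",
]

#: m/z window within which two records are flagged as isobaric
ISOBAR_TOL = 1e-6


def pair_count(n: int) -> int:
    """Number of unordered peptide pairs, homodimers included: (n^2 + n)/2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return (n * n + n) // 2


@dataclass(frozen=True)
class SpeciesRecord:
    """One database entry: a crosslinked or linear (modified) species."""

    annotation: str
    kind: str  # "crosslink" | "linear"
    link: str | None
    neutral_mass: float
    mh: float  # singly protonated m/z
    species: CrosslinkSpecies | PeptideSpec
    isobaric_with: tuple[str, ...] = ()
    isobaric_links: tuple[str, ...] = ()  # link types of the isobaric partners

    @property
    def sites_1based(self) -> tuple[int, int] | None:
        if self.kind != "crosslink":
            return None
        s = self.species
        return (s.site_a + 1, s.site_b + 1)


@dataclass
class CandidateDatabase:
    """m/z-sorted species records with enumeration provenance."""

    records: list[SpeciesRecord]
    link_types: tuple[str, ...]
    mod_rules: tuple[str, ...]
    max_spare_mods: int

    def __post_init__(self) -> None:
        self.records.sort(key=lambda r: (r.mh, r.annotation))
        self._mhs = [r.mh for r in self.records]
        self._flag_isobars()

    def _flag_isobars(self) -> None:
        groups: list[list[int]] = []
        for i, r in enumerate(self.records):
            if groups and abs(r.mh - self.records[groups[-1][-1]].mh) <= ISOBAR_TOL:
                groups[-1].append(i)
            else:
                groups.append([i])
        for grp in groups:
            if len(grp) < 2:
                continue
            for i in grp:
                others = [
                    self.records[j]
                    for j in grp
                    if self.records[j].annotation != self.records[i].annotation
                    or j != i
                ]
                others = [r for r in others if r is not self.records[i]]
                object.__setattr__(
                    self.records[i],
                    "isobaric_with",
                    tuple(r.annotation for r in others),
                )
                object.__setattr__(
                    self.records[i],
                    "isobaric_links",
                    tuple(r.link or "linear" for r in others),
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def query(self, probe_mz: float, tol: float) -> list[SpeciesRecord]:
        return query(self, probe_mz, tol)

    def to_tsv(self) -> str:
        """Serialize as TSV, one row per species (1-based sites)."""
        header = "annotation\tkind\tlink\tsites\tmodifications\tneutral_mass\tmh"
        rows = [header]
        for r in self.records:
            if r.kind == "crosslink":
                s = r.species
                sites = f"{s.site_a + 1}-{s.site_b + 1}"
                mods = ";".join(
                    f"a:{i + 1}:{m}" for i, m in s.peptide_a.modifications
                ) + (";" if s.peptide_a.modifications and s.peptide_b.modifications else "") + ";".join(
                    f"b:{i + 1}:{m}" for i, m in s.peptide_b.modifications
                )
            else:
                sites = "-"
                mods = ";".join(f"{i + 1}:{m}" for i, m in r.species.modifications)
            rows.append(
                f"{r.annotation}\t{r.kind}\t{r.link or '-'}\t{sites}\t{mods or '-'}"
                f"\t{r.neutral_mass:.6f}\t{r.mh:.6f}"
            )
        return "\n".join(rows) + "\n"


def _site_mod_options(p: PeptideSpec, mod_rules: Sequence[str]) -> list[list[tuple[tuple[int, str], ...]]]:
    """Per-site legal modification stacks (each stack applied in order)."""
    options: list[list[tuple[tuple[int, str], ...]]] = []
    prot = dict(p.side_protections)
    for i, res in enumerate(p.sequence):
        stacks: list[tuple[tuple[int, str], ...]] = [()]
        if res == "R" and prot.get(i) == "arg_NO2" and "arg_deprotect_deltaOH" in mod_rules:
            stacks.append(((i, "arg_deprotect_deltaOH"),))
            if "dha_from_deprotected_arg" in mod_rules:
                stacks.append(((i, "arg_deprotect_deltaOH"), (i, "dha_from_deprotected_arg")))
        if res == "S":
            if "ser_acetyl" in mod_rules:
                stacks.append(((i, "ser_acetyl"),))
            if "dha_from_ser" in mod_rules:
                stacks.append(((i, "dha_from_ser"),))
        if res == "C" and "dha_from_cys" in mod_rules:
            stacks.append(((i, "dha_from_cys"),))
        options.append(stacks)
    return options


def enumerate_modified_variants(
    p: PeptideSpec, mod_rules: Sequence[str], max_mods: int
) -> list[PeptideSpec]:
    """All legal concurrently-modified forms of a peptide, up to ``max_mods``.

    The unmodified peptide is always first; order is deterministic.
    """
    variants: list[PeptideSpec] = []
    for combo in product(*_site_mod_options(p, mod_rules)):
        mods = tuple(m for stack in combo for m in stack)
        if len(mods) > max_mods:
            continue
        variants.append(apply_modifications(p, mods))
    variants.sort(key=lambda v: (len(v.modifications), v.modifications))
    return variants


def _donor_sites(p: PeptideSpec, link: str) -> list[int]:
    sites = []
    for i, res in enumerate(p.sequence):
        if res not in DONOR_RESIDUES[link]:
            continue
        if p.has_dha(i):
            continue  # already eliminated, cannot donate again
        if res == "S" and "ser_acetyl" in p.mods_at(i):
            continue
        if res == "R" and not p.is_deprotected_arg(i):
            continue
        sites.append(i)
    return sites


def _acceptor_sites(p: PeptideSpec, link: str) -> list[int]:
    return [
        i
        for i, res in enumerate(p.sequence)
        if res in ACCEPTOR_RESIDUES[link] and not p.has_dha(i)
    ]


def _variant_key(p: PeptideSpec) -> tuple:
    return (p.display_name, p.sequence, p.modifications)


def enumerate_species(
    peptides: Sequence[PeptideSpec],
    link_types: Sequence[str] = LINK_TYPES,
    mod_rules: Sequence[str] = tuple(MODIFICATIONS),
    max_spare_mods: int = 2,
    max_mods_per_peptide: int = 3,
    include_linear: bool = True,
) -> CandidateDatabase:
    """Build the full candidate database for a peptide set.

    Every (unordered pair, link type, donor site, acceptor site,
    modification state) combination is emitted once.  Spare modifications —
    modifications on residues outside the bridge — are capped at
    ``max_spare_mods`` per crosslinked species; linear species may carry up
    to ``max_mods_per_peptide`` modifications.
    """
    if not peptides:
        raise ValueError("peptide set must be nonempty")
    if max_spare_mods < 0:
        raise ValueError("max_spare_mods must be >= 0")

    records: list[SpeciesRecord] = []
    all_variants: list[PeptideSpec] = []
    for p in sorted(peptides, key=lambda q: q.display_name):
        vs = enumerate_modified_variants(p, mod_rules, max_mods_per_peptide)
        all_variants.extend(vs)
        if include_linear:
            for v in vs:
                m = peptide_mass(v)
                records.append(
                    SpeciesRecord(
                        annotation=_linear_annotation(v),
                        kind="linear",
                        link=None,
                        neutral_mass=m,
                        mh=mz(m),
                        species=v,
                    )
                )

    seen: set[tuple] = set()
    for donor, acceptor in product(all_variants, repeat=2):
        for link in link_types:
            for sa in _donor_sites(donor, link):
                for sb in _acceptor_sites(acceptor, link):
                    if (
                        len(donor.modifications) + len(acceptor.modifications)
                        > max_spare_mods
                    ):
                        continue
                    key = (link, _variant_key(donor), sa, _variant_key(acceptor), sb)
                    if link in ("disulfide", "lanthionine"):
                        # symmetric bridges: collapse (A,B) with (B,A)
                        key = (
                            link,
                            *sorted([(_variant_key(donor), sa), (_variant_key(acceptor), sb)]),
                        )
                    if key in seen:
                        continue
                    seen.add(key)
                    try:
                        sp = CrosslinkSpecies(donor, acceptor, link, sa, sb)
                    except ChemError:
                        continue
                    m = crosslink_mass(sp)
                    records.append(
                        SpeciesRecord(
                            annotation=sp.annotation,
                            kind="crosslink",
                            link=link,
                            neutral_mass=m,
                            mh=mz(m),
                            species=sp,
                        )
                    )
    return CandidateDatabase(
        records=records,
        link_types=tuple(link_types),
        mod_rules=tuple(mod_rules),
        max_spare_mods=max_spare_mods,
    )


def _linear_annotation(p: PeptideSpec) -> str:
    tags = []
    for i, res in enumerate(p.sequence):
        mods = p.mods_at(i)
        if p.has_dha(i):
            tags.append("[DHA]")
        elif "ser_acetyl" in mods:
            tags.append("S(Ac)")
        else:
            tags.append(res)
    seq = "".join(tags)
    if any("arg_deprotect_deltaOH" in p.mods_at(i) for i in range(len(p.sequence))):
        seq += "(mod)"
    elif any(
        prot == "arg_NO2" and "arg_deprotect_deltaOH" not in p.mods_at(i)
        for i, prot in p.side_protections
    ):
        seq += "(NO2)"
    return seq


def query(db: CandidateDatabase, probe_mz: float, tol: float) -> list[SpeciesRecord]:
    """All records with |theoretical [M+H]+ − probe| <= tol, nearest first.

    Ties broken by annotation string for stability.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    lo = bisect.bisect_left(db._mhs, probe_mz - tol)
    hi = bisect.bisect_right(db._mhs, probe_mz + tol)
    hits = db.records[lo:hi]
    return sorted(hits, key=lambda r: (abs(r.mh - probe_mz), r.annotation))
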