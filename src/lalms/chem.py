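"""Monoisotopic mass arithmetic for protected, modified and crosslinked peptides.

Model peptides used to study alkali/heat-induced crosslinking carry terminal
protecting groups (N-terminal acetyl, C-terminal amide or nitro-protected
arginine) and acquire concurrent modifications during treatment: loss of the
guanidino protecting group from arginine, serine acetylation, and
dehydroalanine (DHA) formation by beta-elimination from Ser (-H2O), Cys
(-H2S) or the hydroxyl-bearing deprotected arginine (-H2O).  DHA is the
reactive intermediate of both lysinoalanine (Lys epsilon-amine addition) and
lanthionine (Cys thiol addition); a disulfide is the third crosslink type
handled here.

All masses are neutral monoisotopic Da unless a function says otherwise;
reported ions are singly charged (MALDI convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

__all__ = [
    "AA_MONO",
    "PROTON",
    "H",
    "H2O",
    "H2S",
    "S",
    "CH2",
    "AMIDE",
    "ACETYL",
    "ARG_NO2",
    "ARG_DEPROTECT",
    "SODIUM",
    "NA_MINUS_H",
    "Modification",
    "MODIFICATIONS",
    "PeptideSpec",
    "CrosslinkSpecies",
    "LINK_TYPES",
    "peptide_mass",
    "residue_site_mass",
    "apply_modifications",
    "link_delta",
    "crosslink_mass",
    "mz",
]

# Standard monoisotopic residue masses (Da).
AA_MONO: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

PROTON = 1.007276  # H+ (electron mass removed)
H = 1.007825  # hydrogen atom
H2O = 18.010565
H2S = 33.987721
S = 31.972071
CH2 = 14.015650
AMIDE = -0.984016  # C-terminal amide vs free acid (NH2 for OH)
ACETYL = 42.010565
ARG_NO2 = 44.985078  # guanidino nitration: NO2 for H
NA_MINUS_H = 21.981944
SODIUM = 22.989218  # Na+ cation

# Net formula change of the treatment-induced arginine modification:
# the NO2-protected guanidino group loses CH2N4O2 and gains O (a delta-OH
# remains on the side chain).  -86.022861 Da relative to the protected form.
ARG_DEPROTECT = -86.022861

NTermState = Literal["free", "acetyl"]
CTermState = Literal["free_acid", "amide"]

_N_TERM_DELTA = {"free": 0.0, "acetyl": ACETYL}
_C_TERM_DELTA = {"free_acid": 0.0, "amide": AMIDE}
_PROTECTION_DELTA = {"arg_NO2": ARG_NO2}

_DHA_MODS = frozenset({"dha_from_ser", "dha_from_cys", "dha_from_deprotected_arg"})


@dataclass(frozen=True)
class Modification:
    """A named site modification with its mass delta and applicability rule."""

    name: str
    delta: float
    allowed_residue: str
    requires: str | None = None  # modification that must already be on the site


MODIFICATIONS: dict[str, Modification] = {
    m.name: m
    for m in (
        Modification("arg_deprotect_deltaOH", ARG_DEPROTECT, "R"),
        Modification("ser_acetyl", ACETYL, "S"),
        Modification("dha_from_ser", -H2O, "S"),
        Modification("dha_from_cys", -H2S, "C"),
        Modification("dha_from_deprotected_arg", -H2O, "R", requires="arg_deprotect_deltaOH"),
    )
}


class ChemError(ValueError):
    """Raised for invalid residues, sites or modification combinations."""


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide with terminal groups, side-chain protections and modifications.

    Site indices are 0-based internally.  ``modifications`` is an ordered list
    of ``(site, modification_name)`` pairs; the total mass is independent of
    the order in which they were applied.
    """

    sequence: str
    name: str = ""
    n_term: NTermState = "free"
    c_term: CTermState = "free_acid"
    side_protections: tuple[tuple[int, str], ...] = ()
    modifications: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ChemError("empty sequence")
        for res in self.sequence:
            if res not in AA_MONO:
                raise ChemError(f"unknown residue code {res!r}")
        if self.n_term not in _N_TERM_DELTA:
            raise ChemError(f"unknown N-terminal state {self.n_term!r}")
        if self.c_term not in _C_TERM_DELTA:
            raise ChemError(f"unknown C-terminal state {self.c_term!r}")
        seen: set[int] = set()
        for site, prot in self.side_protections:
            self._check_site(site)
            if prot not in _PROTECTION_DELTA:
                raise ChemError(f"unknown protection {prot!r}")
            if site in seen:
                raise ChemError(f"multiple protections at site {site}")
            seen.add(site)
        for i, (site, mod) in enumerate(self.modifications):
            self._validate_mod(site, mod, upto=i)

    def _check_site(self, site: int) -> None:
        if not 0 <= site < len(self.sequence):
            raise ChemError(
                f"site {site} out of range for {self.sequence!r} (0-based)"
            )

    def _validate_mod(self, site: int, mod_name: str, upto: int | None = None) -> None:
        self._check_site(site)
        mod = MODIFICATIONS.get(mod_name)
        if mod is None:
            raise ChemError(f"unknown modification {mod_name!r}")
        if self.sequence[site] != mod.allowed_residue:
            raise ChemError(
                f"{mod_name} applies to {mod.allowed_residue}, "
                f"site {site} is {self.sequence[site]}"
            )
        prior = [m for s, m in self.modifications[: len(self.modifications) if upto is None else upto] if s == site]
        if mod_name in prior:
            raise ChemError(f"{mod_name} already applied at site {site}")
        if mod.requires is not None and mod.requires not in prior:
            raise ChemError(f"{mod_name} at site {site} requires prior {mod.requires}")
        if mod.requires is None and mod_name == "arg_deprotect_deltaOH":
            if dict(self.side_protections).get(site) != "arg_NO2":
                raise ChemError("arg_deprotect_deltaOH requires an NO2-protected arginine")
        # DHA consumes the site: no second DHA, and no DHA on acetylated Ser
        if mod_name in _DHA_MODS and any(m in _DHA_MODS for m in prior):
            raise ChemError(f"site {site} already converted to dehydroalanine")
        if mod_name == "dha_from_ser" and "ser_acetyl" in prior:
            raise ChemError("acetylated serine cannot eliminate to dehydroalanine")
        if mod_name == "ser_acetyl" and any(m in _DHA_MODS for m in prior):
            raise ChemError("cannot acetylate a dehydroalanine site")

    # -- convenience -------------------------------------------------------

    def mods_at(self, site: int) -> tuple[str, ...]:
        return tuple(m for s, m in self.modifications if s == site)

    def has_dha(self, site: int) -> bool:
        return any(m in _DHA_MODS for m in self.mods_at(site))

    def is_deprotected_arg(self, site: int) -> bool:
        return (
            self.sequence[site] == "R"
            and "arg_deprotect_deltaOH" in self.mods_at(site)
        )

    @property
    def display_name(self) -> str:
        return self.name or self.sequence

    def serialize(self) -> str:
        """Plain-text key-value block (1-based indices user-facing)."""
        lines = [
            f"name = {self.display_name}",
            f"sequence = {self.sequence}",
            f"n_term = {self.n_term}",
            f"c_term = {self.c_term}",
        ]
        if self.side_protections:
            prot = ",".join(
                f"{self.sequence[s]}:{s + 1}:{p}" for s, p in self.side_protections
            )
            lines.append(f"protections = {prot}")
        if self.modifications:
            mods = ",".join(f"{s + 1}:{m}" for s, m in self.modifications)
            lines.append(f"modifications = {mods}")
        return "\n".join(lines)

    @classmethod
    def deserialize(cls, block: str) -> "PeptideSpec":
        kv: dict[str, str] = {}
        for line in block.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("["):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        prot = []
        for item in filter(None, kv.get("protections", "").split(",")):
            _res, idx, ptype = item.split(":")
            prot.append((int(idx) - 1, ptype))
        mods = []
        for item in filter(None, kv.get("modifications", "").split(",")):
            idx, mname = item.split(":")
            mods.append((int(idx) - 1, mname))
        return cls(
            sequence=kv["sequence"],
            name=kv.get("name", ""),
            n_term=kv.get("n_term", "free"),  # type: ignore[arg-type]
            c_term=kv.get("c_term", "free_acid"),  # type: ignore[arg-type]
            side_protections=tuple(prot),
            modifications=tuple(mods),
        )


def peptide_mass(p: PeptideSpec) -> float:
    """Neutral monoisotopic mass of a peptide spec.

    Sum of residue masses + H2O + terminal deltas + protection deltas +
    modification deltas.  Pure function of the spec.
    """
    mass = sum(AA_MONO[res] for res in p.sequence) + H2O
    mass += _N_TERM_DELTA[p.n_term] + _C_TERM_DELTA[p.c_term]
    mass += sum(_PROTECTION_DELTA[prot] for _site, prot in p.side_protections)
    mass += sum(MODIFICATIONS[m].delta for _site, m in p.modifications)
    return mass


def residue_site_mass(p: PeptideSpec, site: int) -> float:
    """Effective residue mass at a site, protections and modifications riding along."""
    p._check_site(site)
    mass = AA_MONO[p.sequence[site]]
    mass += sum(
        _PROTECTION_DELTA[prot] for s, prot in p.side_protections if s == site
    )
    mass += sum(MODIFICATIONS[m].delta for s, m in p.modifications if s == site)
    return mass


def apply_modifications(
    p: PeptideSpec, mods: Iterable[tuple[int, str]]
) -> PeptideSpec:
    """Return a new spec with ``mods`` appended, validating each in turn."""
    out = p
    for site, mod_name in mods:
        out._validate_mod(site, mod_name)
        out = replace(out, modifications=out.modifications + ((site, mod_name),))
    return out


# -- crosslinks -------------------------------------------------------------

LINK_TYPES = ("disulfide", "lanthionine", "lysinoalanine")

#: residues that can donate the DHA intermediate, per link type
DONOR_RESIDUES = {
    "disulfide": ("C",),
    "lanthionine": ("C",),
    "lysinoalanine": ("C", "S", "R"),  # R only after deprotection
}
ACCEPTOR_RESIDUES = {
    "disulfide": ("C",),
    "lanthionine": ("C",),
    "lysinoalanine": ("K",),
}


def link_delta(link: str, donor_peptide: PeptideSpec, donor_site: int) -> float:
    """Mass delta of forming a crosslink, relative to the two intact peptides.

    Disulfide loses two hydrogens.  Lanthionine and Cys-derived lysinoalanine
    lose H2S (beta-elimination of the thiol); Ser- or hydroxyl-arginine-derived
    lysinoalanine loses H2O.  The DHA-addition step itself is mass neutral, so
    the elimination loss is the whole delta.
    """
    if link == "disulfide":
        return -2 * H
    res = donor_peptide.sequence[donor_site]
    if link == "lanthionine":
        if res != "C":
            raise ChemError("lanthionine donor must be cysteine")
        return -H2S
    if link == "lysinoalanine":
        if res == "C":
            return -H2S
        if res == "S":
            return -H2O
        if res == "R" and donor_peptide.is_deprotected_arg(donor_site):
            return -H2O
        raise ChemError(
            f"lysinoalanine donor must be Cys, Ser or deprotected Arg, got {res}"
        )
    raise ChemError(f"unknown crosslink type {link!r}")


@dataclass(frozen=True)
class CrosslinkSpecies:
    """Two peptides joined by a typed bridge, plus spare (non-bridge) mods.

    ``peptide_a`` is the donor chain (contributes the DHA intermediate or the
    first half-cystine); ``peptide_b`` the acceptor.  ``spare_mods`` are
    modifications on residues outside the bridge, given as
    ``(chain, site, modification_name)`` with chain ``"a"`` or ``"b"``.
    """

    peptide_a: PeptideSpec
    peptide_b: PeptideSpec
    link: str
    site_a: int
    site_b: int
    spare_mods: tuple[tuple[str, int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.link not in LINK_TYPES:
            raise ChemError(f"unknown crosslink type {self.link!r}")
        self.peptide_a._check_site(self.site_a)
        self.peptide_b._check_site(self.site_b)
        res_a = self.peptide_a.sequence[self.site_a]
        res_b = self.peptide_b.sequence[self.site_b]
        if res_a not in DONOR_RESIDUES[self.link]:
            raise ChemError(f"{res_a} cannot donate a {self.link} bridge")
        if res_a == "R" and not self.peptide_a.is_deprotected_arg(self.site_a):
            raise ChemError("arginine donor requires the deprotection modification")
        if res_b not in ACCEPTOR_RESIDUES[self.link]:
            raise ChemError(f"{res_b} cannot accept a {self.link} bridge")
        for chain, site, _mod in self.spare_mods:
            if chain not in ("a", "b"):
                raise ChemError(f"spare mod chain must be 'a' or 'b', got {chain!r}")
            if (chain == "a" and site == self.site_a) or (
                chain == "b" and site == self.site_b
            ):
                raise ChemError("spare modification collides with the bridge site")
        # validate applicability eagerly
        self.chain_with_spares("a")
        self.chain_with_spares("b")

    def chain_with_spares(self, chain: str) -> PeptideSpec:
        """The peptide of one chain with that chain's spare mods applied."""
        p = self.peptide_a if chain == "a" else self.peptide_b
        return apply_modifications(
            p, [(site, m) for c, site, m in self.spare_mods if c == chain]
        )

    @property
    def delta(self) -> float:
        return link_delta(self.link, self.peptide_a, self.site_a)

    @property
    def annotation(self) -> str:
        """Human-readable annotation, bridge residues marked with asterisks."""

        def mark(p: PeptideSpec, site: int, chain: str) -> str:
            chars = []
            for i, res in enumerate(p.sequence):
                tag = res
                spared = any(
                    c == chain and s == i and m in _DHA_MODS
                    for c, s, m in self.spare_mods
                ) or p.has_dha(i)
                if spared:
                    tag = "[DHA]"
                elif "ser_acetyl" in p.mods_at(i):
                    tag = "S(Ac)"
                if i == site:
                    tag = f"*{res}*"
                chars.append(tag)
            seq = "".join(chars)
            if any("arg_deprotect_deltaOH" in p.mods_at(i) for i in range(len(p.sequence))):
                seq += "(mod)"
            elif any(
                prot == "arg_NO2" and "arg_deprotect_deltaOH" not in p.mods_at(i)
                for i, prot in p.side_protections
            ):
                seq += "(NO2)"
            return seq

        return (
            f"{mark(self.peptide_a, self.site_a, 'a')}"
            f" - {mark(self.peptide_b, self.site_b, 'b')}"
        )


def crosslink_mass(s: CrosslinkSpecies) -> float:
    """Neutral mass: mass(a) + mass(b) + link delta + spare-mod deltas."""
    return (
        peptide_mass(s.chain_with_spares("a"))
        + peptide_mass(s.chain_with_spares("b"))
        + s.delta
    )


def mz(neutral_mass: float, adduct: str = "proton") -> float:
    """Singly charged m/z for a neutral mass ([M+H]+ or [M+Na]+)."""
    if adduct == "proton":
        return neutral_mass + PROTON
    if adduct == "sodium":
        return neutral_mass + SODIUM
    raise ChemError(f"unsupported adduct {adduct!r} (singly charged proton/sodium only)")
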