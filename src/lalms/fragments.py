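"""Theoretical MS/MS ion generation for linear and crosslinked peptides.

Beyond the standard b/y backbone series, crosslinked species yield three
families of structure-informative ions:

* intact-bridge fragments — backbone cleavages on one chain while the
  crosslink (and therefore the entire partner chain) stays attached;
* the lysinoalanine diagnostic pair — cleavage between the alpha- and
  beta-carbon of the bridge, leaving the donor chain with its crosslink
  residue reduced to a glycine-like residue (fragment i) and the acceptor
  chain with an extra CH2 on the lysine epsilon-amine (fragment ii);
* the disulfide triplet — the classic thiol / dehydroalanine / persulfide
  three-peak pattern around each constituent chain.

Because MALDI CID mixes even-electron and radical channels, hydrogen
bookkeeping of the diagnostic pair is not a single convention: candidates
are emitted for each plausible H-transfer variant and the matcher picks the
nearest.  All ions are singly charged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .chem import (
    AA_MONO,
    CH2,
    H,
    H2O,
    H2S,
    PROTON,
    S,
    ChemError,
    CrosslinkSpecies,
    PeptideSpec,
    crosslink_mass,
    mz,
    peptide_mass,
    residue_site_mass,
)

__all__ = [
    "TheoreticalIon",
    "by_ions",
    "crosslinked_by_ions",
    "diagnostic_pair",
    "disulfide_triplet",
    "companion_dha_mz",
    "site_localizing_ions",
]

#: ion-class priority used by the matcher for tie-breaking (low = preferred)
ION_CLASS_PRIORITY = {
    "b": 0,
    "y": 0,
    "precursor": 1,
    "diag_i": 2,
    "diag_ii": 2,
    "site_localizer": 2,
    "triplet": 3,
    "companion": 3,
}


@dataclass(frozen=True)
class TheoreticalIon:
    """A predicted singly charged fragment ion."""

    mz: float
    ion_class: str  # b, y, precursor, diag_i, diag_ii, triplet, companion, site_localizer
    chain: str | None = None  # "a", "b", "both" or None for linear peptides
    ordinal: int | None = None  # series index for b/y
    variant: str = "even_electron"
    annotation: str = ""
    crosslinked: bool = False  # True if the partner chain rides on this fragment

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"non-positive ion m/z: {self.mz}")


def _prefix_masses(p: PeptideSpec) -> list[float]:
    out, acc = [], 0.0
    for i in range(len(p.sequence)):
        acc += residue_site_mass(p, i)
        out.append(acc)
    return out


def by_ions(p: PeptideSpec, chain: str | None = None) -> list[TheoreticalIon]:
    """Plain b1..b(n-1) and y1..y(n-1) ions; modifications ride with residues.

    b_k = sum(residues 1..k) + N-terminal delta + proton;
    y_k = sum(residues n-k+1..n) + H2O + C-terminal delta + proton.
    """
    n = len(p.sequence)
    if n < 2:
        raise ChemError("peptide must have at least 2 residues to fragment")
    full = peptide_mass(p)
    prefix = _prefix_masses(p)
    nterm_delta = full - H2O - prefix[-1] - _cterm_delta(p)
    ions: list[TheoreticalIon] = []
    tag = f"{chain}:" if chain else ""
    for k in range(1, n):
        b = prefix[k - 1] + nterm_delta + PROTON
        y = (prefix[-1] - prefix[n - k - 1]) + H2O + _cterm_delta(p) + PROTON
        ions.append(TheoreticalIon(b, "b", chain, k, annotation=f"{tag}b{k}"))
        ions.append(TheoreticalIon(y, "y", chain, k, annotation=f"{tag}y{k}"))
    return ions


def _cterm_delta(p: PeptideSpec) -> float:
    return -0.984016 if p.c_term == "amide" else 0.0


def crosslinked_by_ions(s: CrosslinkSpecies) -> list[TheoreticalIon]:
    """b/y ions of both chains; fragments containing the bridge site carry
    the full partner chain plus the link delta."""
    ions: list[TheoreticalIon] = []
    chains = {"a": (s.chain_with_spares("a"), s.site_a), "b": (s.chain_with_spares("b"), s.site_b)}
    for chain, (p, site) in chains.items():
        partner = chains["b" if chain == "a" else "a"][0]
        partner_mass = peptide_mass(partner) + s.delta
        n = len(p.sequence)
        for ion in by_ions(p, chain=chain):
            k = ion.ordinal
            covers = site < k if ion.ion_class == "b" else site >= n - k
            if covers:
                ions.append(
                    TheoreticalIon(
                        ion.mz + partner_mass,
                        ion.ion_class,
                        chain,
                        k,
                        annotation=ion.annotation + "+P",
                        crosslinked=True,
                    )
                )
            else:
                ions.append(ion)
    return ions


def diagnostic_pair(s: CrosslinkSpecies) -> dict[str, list[TheoreticalIon]]:
    """Candidate ions for the lysinoalanine alpha-beta cleavage pair.

    Fragment i: the donor chain after the bridge CH2 departs with the
    partner — the crosslink residue is reduced to glycine; canonical m/z is
    the glycine-substituted chain plus a proton, with +-1 H radical
    variants.  Fragment ii: the acceptor chain retaining an extra CH2 on the
    lysine epsilon-amine; candidates at M+CH2 and M+CH2-H, each also with an
    added proton.
    """
    if s.link != "lysinoalanine":
        raise ChemError("diagnostic pair is defined for lysinoalanine only")
    donor = s.chain_with_spares("a")
    # donor chain in its bridged state, minus the CH2 that departs with the
    # partner, plus the two H restored on cleavage; for Cys and Ser donors
    # this equals the chain with the crosslink residue replaced by glycine
    m_i = peptide_mass(donor) + s.delta - CH2 + 2 * H
    i_canonical = m_i + PROTON
    i_ions = [
        TheoreticalIon(i_canonical, "diag_i", "a", variant="even_electron", annotation="i"),
        TheoreticalIon(i_canonical + H, "diag_i", "a", variant="radical_plus_H", annotation="i+H"),
        TheoreticalIon(i_canonical - H, "diag_i", "a", variant="radical_minus_H", annotation="i-H"),
    ]
    m_ii = peptide_mass(s.chain_with_spares("b"))
    ii_ions = [
        TheoreticalIon(m_ii + CH2, "diag_ii", "b", variant="plus_CH2", annotation="ii"),
        TheoreticalIon(m_ii + CH2 - H, "diag_ii", "b", variant="plus_CH2_minus_H", annotation="ii-H"),
        TheoreticalIon(
            m_ii + CH2 + PROTON, "diag_ii", "b", variant="plus_CH2_protonated", annotation="ii+H+"
        ),
        TheoreticalIon(
            m_ii + CH2 - H + PROTON,
            "diag_ii",
            "b",
            variant="plus_CH2_minus_H_protonated",
            annotation="ii-H+H+",
        ),
    ]
    return {"i": i_ions, "ii": ii_ions}


def disulfide_triplet(s: CrosslinkSpecies) -> list[TheoreticalIon]:
    """Triplet marker ions per chain: protonated thiol form flanked by the
    dehydroalanine form (-H2S) and the persulfide form (+S)."""
    if s.link != "disulfide":
        raise ChemError("triplet marker ions are defined for disulfide only")
    ions = []
    for chain in ("a", "b"):
        m_sh = peptide_mass(s.chain_with_spares(chain))
        for delta, label in ((-H2S, "dha"), (0.0, "thiol"), (S, "persulfide")):
            ions.append(
                TheoreticalIon(
                    m_sh + delta + PROTON,
                    "triplet",
                    chain,
                    variant=label,
                    annotation=f"{chain}:{label}",
                )
            )
    return ions


def companion_dha_mz(s: CrosslinkSpecies) -> float | None:
    """Precursor satellite from dehydroalanine formation on a spare residue.

    Only a lysinoalanine-linked species can have a non-bridged cysteine (or
    serine) free to eliminate: the satellite sits 33.988 Da (Cys) or
    18.011 Da (Ser) below the precursor.  Lanthionine consumes both thiols,
    so no satellite exists — this is the discriminator between the two
    isobaric crosslinks.  Returns None when no spare site is available.
    """
    if s.link != "lysinoalanine":
        return None
    precursor = mz(crosslink_mass(s))
    for chain in ("a", "b"):
        p = s.chain_with_spares(chain)
        bridge = s.site_a if chain == "a" else s.site_b
        for i, res in enumerate(p.sequence):
            if i == bridge or p.has_dha(i):
                continue
            if res == "C":
                return precursor - H2S
    for chain in ("a", "b"):
        p = s.chain_with_spares(chain)
        bridge = s.site_a if chain == "a" else s.site_b
        for i, res in enumerate(p.sequence):
            if i == bridge or p.has_dha(i) or "ser_acetyl" in p.mods_at(i):
                continue
            if res == "S":
                return precursor - H2O
    return None


def site_localizing_ions(
    s: CrosslinkSpecies,
    alternatives: Sequence[CrosslinkSpecies],
    resolution: float = 1e-4,
) -> list[TheoreticalIon]:
    """Intact-bridge b/y ions unique to one site variant among isobaric twins.

    Site-ambiguous species (same peptides, same precursor m/z, different
    bridge site) share most fragments; the returned set difference is the
    evidence that localizes the bridge.  Identical twins give an empty set.
    """
    own = crosslinked_by_ions(s)
    other_mzs: list[float] = []
    for alt in alternatives:
        other_mzs.extend(ion.mz for ion in crosslinked_by_ions(alt))
    other_mzs.sort()

    def in_others(x: float) -> bool:
        import bisect

        j = bisect.bisect_left(other_mzs, x - resolution)
        return j < len(other_mzs) and other_mzs[j] <= x + resolution

    return [
        TheoreticalIon(
            ion.mz,
            "site_localizer",
            ion.chain,
            ion.ordinal,
            ion.variant,
            ion.annotation + "!",
            ion.crosslinked,
        )
        for ion in own
        if not in_others(ion.mz)
    ]
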