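"""Peak-list matching and the identification / confirmation / disambiguation rules.

The identification workflow mirrors manual de novo annotation of MALDI
spectra of model crosslinked peptides:

1. precursor matching — each MS peak is compared against the candidate
   database within the MS tolerance (default 0.2 Da);
2. sequence confirmation — a hit is confirmed when at least *x* distinct b
   or y ions (plain or intact-bridge) match the MS/MS spectrum within the
   MS/MS tolerance (default 0.8 Da), where *x* is the number of residues in
   the shorter constituent peptide;
3. disambiguation — isobaric lysinoalanine/lanthionine hits are resolved by
   the spare-dehydroalanine companion peak 33.99 Da below the precursor
   (present: lysinoalanine; absent: ambiguous, or "lanthionine-consistent"
   when the diagnostic pair is also absent from MS/MS);
4. replication — a species qualifies only when confirmed in every replicate
   of a condition.

Intensity never influences identification; it is used only downstream for
trend analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .chem import CrosslinkSpecies, PeptideSpec
from .database import CandidateDatabase, SpeciesRecord, query
from .fragments import (
    ION_CLASS_PRIORITY,
    TheoreticalIon,
    by_ions,
    companion_dha_mz,
    crosslinked_by_ions,
    diagnostic_pair,
)

__all__ = [
    "Condition",
    "PeakList",
    "Tolerances",
    "PrecursorHit",
    "IonMatch",
    "IdentificationResult",
    "match_ms",
    "confirm_sequence",
    "disambiguate",
    "detect_diagnostic",
    "replicate_filter",
]


@dataclass(frozen=True)
class Condition:
    """Treatment condition attached to a spectrum."""

    pH: float | None = None
    days: float | None = None
    replicate_id: str = "1"
    sample_name: str = ""

    @property
    def level_key(self) -> tuple:
        return (self.pH, self.days)


@dataclass(frozen=True)
class PeakList:
    """A centroided peak list: ascending m/z with non-negative intensities."""

    mz: np.ndarray
    intensity: np.ndarray
    level: str = "MS"  # "MS" | "MSMS"
    precursor_mz: float | None = None
    condition: Condition = field(default_factory=Condition)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(inten < 0):
            raise ValueError("negative intensity")
        order = np.argsort(mz, kind="stable")
        object.__setattr__(self, "mz", mz[order])
        object.__setattr__(self, "intensity", inten[order])
        if self.level not in ("MS", "MSMS"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.level == "MSMS" and self.precursor_mz is None:
            raise ValueError("MSMS peak list requires precursor_mz")

    def __len__(self) -> int:
        return len(self.mz)

    def nearest_peak(self, target: float, tol: float) -> tuple[float, float] | None:
        """(m/z, intensity) of the nearest peak within tol, or None."""
        if len(self.mz) == 0:
            return None
        i = int(np.searchsorted(self.mz, target))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(self.mz):
                d = abs(self.mz[j] - target)
                if d <= tol and (best is None or d < best[0]):
                    best = (d, j)
        if best is None:
            return None
        j = best[1]
        return float(self.mz[j]), float(self.intensity[j])


@dataclass(frozen=True)
class Tolerances:
    """Instrument error tolerances (Da)."""

    ms_tol: float = 0.2
    msms_tol: float = 0.8

    def __post_init__(self) -> None:
        if self.ms_tol <= 0 or self.msms_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class PrecursorHit:
    record: SpeciesRecord
    observed_mz: float
    intensity: float

    @property
    def delta(self) -> float:
        return self.observed_mz - self.record.mh


@dataclass(frozen=True)
class IonMatch:
    ion: TheoreticalIon
    observed_mz: float

    @property
    def delta(self) -> float:
        return self.observed_mz - self.ion.mz


@dataclass(frozen=True)
class IdentificationResult:
    record: SpeciesRecord
    precursor: PrecursorHit | None
    matched_ions: tuple[IonMatch, ...] = ()
    required_by_count: int = 0
    confirmed: bool = False
    disambiguation: str = "n/a"  # LAL | lanthionine-consistent | ambiguous | n/a
    site_verdict: str = "n/a"
    replicate_status: str = "single"  # single | duplicated
    condition: Condition = field(default_factory=Condition)

    @property
    def by_ion_count(self) -> int:
        return sum(1 for m in self.matched_ions if m.ion.ion_class in ("b", "y"))


def match_ms(pl: PeakList, db: CandidateDatabase, tol: Tolerances) -> list[PrecursorHit]:
    """Query every MS peak against the database within the MS tolerance."""
    if pl.level != "MS":
        raise ValueError("match_ms expects an MS-level peak list")
    hits: list[PrecursorHit] = []
    for m, inten in zip(pl.mz, pl.intensity):
        for rec in query(db, float(m), tol.ms_tol):
            hits.append(PrecursorHit(rec, float(m), float(inten)))
    return hits


def _theoretical_backbone(species: CrosslinkSpecies | PeptideSpec) -> list[TheoreticalIon]:
    if isinstance(species, CrosslinkSpecies):
        return crosslinked_by_ions(species)
    return by_ions(species)


def _required_count(species: CrosslinkSpecies | PeptideSpec) -> int:
    if isinstance(species, CrosslinkSpecies):
        return min(len(species.peptide_a.sequence), len(species.peptide_b.sequence))
    return len(species.sequence)


def greedy_assign(
    ions: Sequence[TheoreticalIon], pl: PeakList, tol: float
) -> list[IonMatch]:
    """Greedy nearest-delta assignment; each peak and each ion used once.

    Candidate pairs are sorted by |delta|, then by ion-class priority
    (backbone before diagnostic before marker ions), then by annotation for
    determinism.
    """
    pairs: list[tuple[float, int, str, int, int]] = []
    for ii, ion in enumerate(ions):
        lo = int(np.searchsorted(pl.mz, ion.mz - tol))
        hi = int(np.searchsorted(pl.mz, ion.mz + tol, side="right"))
        for pj in range(lo, hi):
            pairs.append(
                (
                    abs(float(pl.mz[pj]) - ion.mz),
                    ION_CLASS_PRIORITY.get(ion.ion_class, 9),
                    ion.annotation,
                    ii,
                    pj,
                )
            )
    pairs.sort()
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    out: list[IonMatch] = []
    for _d, _prio, _anno, ii, pj in pairs:
        if ii in used_ions or pj in used_peaks:
            continue
        used_ions.add(ii)
        used_peaks.add(pj)
        out.append(IonMatch(ions[ii], float(pl.mz[pj])))
    return out


def confirm_sequence(
    msms: PeakList, record: SpeciesRecord, tol: Tolerances
) -> IdentificationResult:
    """Confirm a precursor hit from its MS/MS spectrum.

    Counts distinct matched b/y ions (plain and intact-bridge) and confirms
    when the count reaches the length of the shorter constituent peptide.
    """
    if msms.level != "MSMS":
        raise ValueError("confirm_sequence expects an MSMS-level peak list")
    if abs(msms.precursor_mz - record.mh) > tol.ms_tol:
        raise ValueError(
            f"precursor m/z {msms.precursor_mz} does not match species "
            f"{record.annotation} ({record.mh:.3f}) within {tol.ms_tol} Da"
        )
    ions = _theoretical_backbone(record.species)
    matches = greedy_assign(ions, msms, tol.msms_tol)
    by_count = sum(1 for m in matches if m.ion.ion_class in ("b", "y"))
    required = _required_count(record.species)
    return IdentificationResult(
        record=record,
        precursor=PrecursorHit(record, float(msms.precursor_mz), 0.0),
        matched_ions=tuple(matches),
        required_by_count=required,
        confirmed=by_count >= required,
        condition=msms.condition,
    )


def disambiguate(
    ms: PeakList,
    hit: PrecursorHit | IdentificationResult,
    tol: Tolerances,
    msms: PeakList | None = None,
) -> str:
    """Resolve an isobaric lysinoalanine/lanthionine hit.

    "LAL" when the spare-DHA companion peak is present in MS within the MS
    tolerance.  Without it the call stays "ambiguous" — lanthionine is never
    positively asserted — unless an MS/MS spectrum is supplied and neither
    the companion nor the diagnostic pair is found, in which case the hit is
    reported "lanthionine-consistent".  Non-isobaric hits pass through
    unchanged ("n/a").
    """
    record = hit.record
    other = {"lysinoalanine": "lanthionine", "lanthionine": "lysinoalanine"}
    if (
        not record.isobaric_with
        or record.kind != "crosslink"
        or record.link not in other
        or other[record.link] not in record.isobaric_links
    ):
        return "n/a"
    species = record.species
    if species.link == "lysinoalanine":
        lal_species = species
    else:
        lal_species = None

    companion = companion_dha_mz(lal_species) if lal_species is not None else None
    if companion is None and lal_species is None:
        # lanthionine record: test its LAL twin's companion = precursor - H2S
        from .chem import H2S

        companion = record.mh - H2S
    if companion is not None and ms.nearest_peak(companion, tol.ms_tol) is not None:
        return "LAL"
    if msms is not None and lal_species is not None:
        evidence = detect_diagnostic(msms, record, tol)
        if not evidence:
            return "lanthionine-consistent"
    return "ambiguous"


def detect_diagnostic(
    msms: PeakList, record: SpeciesRecord, tol: Tolerances
) -> list[IonMatch]:
    """Nearest-candidate matches for the diagnostic i/ii pair in an MS/MS list.

    At most one match per fragment class; the candidate variant with the
    smallest |delta| to any peak wins.
    """
    species = record.species if isinstance(record, SpeciesRecord) else record
    cands = diagnostic_pair(species)
    out: list[IonMatch] = []
    for klass in ("i", "ii"):
        best: IonMatch | None = None
        for ion in cands[klass]:
            peak = msms.nearest_peak(ion.mz, tol.msms_tol)
            if peak is None:
                continue
            m = IonMatch(ion, peak[0])
            if best is None or abs(m.delta) < abs(best.delta):
                best = m
        if best is not None:
            out.append(best)
    return out


def replicate_filter(
    results: Iterable[IdentificationResult],
) -> list[IdentificationResult]:
    """Keep species confirmed in every replicate of their condition.

    The replicate universe of a condition is the set of replicate ids seen
    in any result for that (pH, days).  Qualified results are returned with
    ``replicate_status="duplicated"``; the rest are dropped.  Output order
    is deterministic (condition, annotation, replicate).
    """
    results = list(results)
    reps_per_condition: dict[tuple, set[str]] = {}
    confirmed_reps: dict[tuple, set[str]] = {}
    for r in results:
        key = r.condition.level_key
        reps_per_condition.setdefault(key, set()).add(r.condition.replicate_id)
        if r.confirmed:
            confirmed_reps.setdefault((key, r.record.annotation), set()).add(
                r.condition.replicate_id
            )
    out = []
    for r in sorted(
        results,
        key=lambda r: (
            str(r.condition.level_key),
            r.record.annotation,
            r.condition.replicate_id,
        ),
    ):
        if not r.confirmed:
            continue
        key = r.condition.level_key
        if confirmed_reps[(key, r.record.annotation)] >= reps_per_condition[key]:
            out.append(replace(r, replicate_status="duplicated"))
    return out
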