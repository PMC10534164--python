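"""End-to-end identification: MS matching, MS/MS confirmation,
disambiguation, site localization and the duplicate rule, in one call."""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

from .database import CandidateDatabase, SpeciesRecord, query
from .fragments import site_localizing_ions
from .matching import (
    Condition,
    IdentificationResult,
    PeakList,
    Tolerances,
    confirm_sequence,
    detect_diagnostic,
    disambiguate,
    greedy_assign,
    match_ms,
)

__all__ = ["identify_run", "site_twins", "localize_site"]


def site_twins(db: CandidateDatabase, record: SpeciesRecord) -> list[SpeciesRecord]:
    """Isobaric records differing from ``record`` only in the bridge site."""
    if record.kind != "crosslink":
        return []
    s = record.species
    twins = []
    for anno in record.isobaric_with:
        for other in db:
            if other.annotation != anno or other.kind != "crosslink":
                continue
            o = other.species
            if (
                other.link == record.link
                and {o.peptide_a.sequence, o.peptide_b.sequence}
                == {s.peptide_a.sequence, s.peptide_b.sequence}
                and (o.site_a, o.site_b) != (s.site_a, s.site_b)
            ):
                twins.append(other)
    return twins


def localize_site(
    msms: PeakList,
    record: SpeciesRecord,
    twins: Sequence[SpeciesRecord],
    tol: Tolerances,
) -> str:
    """Site verdict for a species with site-ambiguous isobaric twins.

    "localized" when at least one fragment unique to this site variant is
    matched in MS/MS; "ambiguous" otherwise; "n/a" without twins.
    """
    if not twins:
        return "n/a"
    localizers = site_localizing_ions(record.species, [t.species for t in twins])
    matched = greedy_assign(localizers, msms, tol.msms_tol)
    return "localized" if matched else "ambiguous"


def identify_run(
    db: CandidateDatabase,
    ms_lists: Sequence[PeakList],
    msms_lists: Sequence[PeakList],
    tol: Tolerances = Tolerances(),
    require_duplicates: bool = False,
) -> list[IdentificationResult]:
    """Run the full identification workflow over one batch of spectra.

    MS lists provide precursor hits and companion-peak evidence; each MS/MS
    list confirms the database records matching its precursor.  MS and
    MS/MS lists are paired by condition (pH, days, replicate).  With
    ``require_duplicates`` only species confirmed in every replicate of a
    condition survive.
    """
    ms_by_cond: dict[tuple, PeakList] = {}
    for pl in ms_lists:
        ms_by_cond[_cond_key(pl.condition)] = pl

    results: list[IdentificationResult] = []
    for msms in msms_lists:
        candidates = query(db, msms.precursor_mz, tol.ms_tol)
        ms = ms_by_cond.get(_cond_key(msms.condition))
        for rec in candidates:
            res = confirm_sequence(msms, rec, tol)
            if ms is not None:
                verdict = disambiguate(ms, res, tol, msms=msms)
                res = replace(res, disambiguation=verdict)
            twins = site_twins(db, rec)
            res = replace(res, site_verdict=localize_site(msms, rec, twins, tol))
            # record observed precursor intensity from the MS list if present
            if ms is not None:
                peak = ms.nearest_peak(rec.mh, tol.ms_tol)
                if peak is not None and res.precursor is not None:
                    res = replace(
                        res,
                        precursor=replace(
                            res.precursor, observed_mz=peak[0], intensity=peak[1]
                        ),
                    )
            results.append(res)

    if require_duplicates:
        from .matching import replicate_filter

        return replicate_filter(results)
    return results


def _cond_key(c: Condition) -> tuple:
    return (c.pH, c.days, c.replicate_id)
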