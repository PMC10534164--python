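"""Peak matching, sequence confirmation, disambiguation and the duplicate rule."""

import numpy as np
import pytest

from lalms.chem import H2S
from lalms.fragments import crosslinked_by_ions
from lalms.matching import (
    Condition,
    IdentificationResult,
    PeakList,
    Tolerances,
    confirm_sequence,
    detect_diagnostic,
    disambiguate,
    greedy_assign,
    match_ms,
    replicate_filter,
)
from lalms.synth import SimulationPlan, simulate_ms, simulate_msms

TOL = Tolerances()


def _ms(mzs, intensities=None, **cond):
    mzs = np.asarray(mzs, float)
    inten = np.ones_like(mzs) if intensities is None else np.asarray(intensities, float)
    return PeakList(mzs, inten, level="MS", condition=Condition(**cond))


def _msms(mzs, precursor, **cond):
    mzs = np.asarray(mzs, float)
    return PeakList(
        mzs,
        np.ones_like(mzs),
        level="MSMS",
        precursor_mz=precursor,
        condition=Condition(**cond),
    )


class TestPeakList:
    def test_sorts_and_validates(self):
        pl = _ms([300.0, 100.0, 200.0])
        assert list(pl.mz) == [100.0, 200.0, 300.0]
        with pytest.raises(ValueError):
            PeakList(np.array([1.0]), np.array([-1.0]))
        with pytest.raises(ValueError):
            PeakList(np.array([1.0]), np.array([1.0]), level="MSMS")

    def test_nearest_peak(self):
        pl = _ms([100.0, 100.3])
        assert pl.nearest_peak(100.1, 0.2)[0] == 100.0
        assert pl.nearest_peak(100.25, 0.2)[0] == 100.3
        assert pl.nearest_peak(101.0, 0.2) is None


class TestMatchMS:
    def test_isobaric_peak_hits_both_records(self, model_db):
        hits = match_ms(_ms([1869.92]), model_db, TOL)
        links = {h.record.link for h in hits}
        assert {"lysinoalanine", "lanthionine"} <= links

    def test_out_of_tolerance_no_hit(self, model_db):
        assert match_ms(_ms([1869.92 + 0.5]), model_db, TOL) == []

    def test_msms_list_rejected(self, model_db):
        with pytest.raises(ValueError):
            match_ms(_msms([100.0], 1000.0), model_db, TOL)

    def test_planted_spectrum_hit_set_equals_manifest(self, model_db):
        """Fixture-generator ground truth: every planted precursor is hit
        and every hit corresponds to a planted or isobaric record."""
        planted = [r for r in model_db if r.kind == "crosslink"][:50]
        plan = SimulationPlan(
            species=tuple((r, 100.0) for r in planted),
            seed=11,
            jitter_sigma=0.0,
            noise_fraction=0.0,
        )
        pl, manifest = simulate_ms(plan)
        hits = match_ms(pl, model_db, TOL)
        hit_mhs = {round(h.record.mh, 3) for h in hits}
        planted_mhs = {round(m, 3) for m in manifest["theoretical_mz"]}
        assert planted_mhs <= hit_mhs  # all planted recovered
        for h in hits:  # no hit far from any planted peak
            assert any(abs(h.observed_mz - m) <= TOL.ms_tol for m in manifest["planted_mz"])


class TestConfirmSequence:
    def test_all_by_ions_planted_confirms(self, model_db, headline_records):
        rec = headline_records[1591.9]
        ions = crosslinked_by_ions(rec.species)
        spectrum = _msms([i.mz for i in ions], rec.mh)
        res = confirm_sequence(spectrum, rec, TOL)
        assert res.required_by_count == 5  # LLKLF is the shorter peptide
        assert res.confirmed

    def test_four_ions_do_not_confirm(self, model_db, headline_records):
        rec = headline_records[1591.9]
        ions = crosslinked_by_ions(rec.species)[:4]
        res = confirm_sequence(_msms([i.mz for i in ions], rec.mh), rec, TOL)
        assert res.by_ion_count == 4
        assert not res.confirmed

    def test_precursor_mismatch_raises(self, headline_records):
        rec = headline_records[1591.9]
        with pytest.raises(ValueError):
            confirm_sequence(_msms([500.0], rec.mh + 1.0), rec, TOL)

    def test_jittered_spectra_confirm_95_percent(self, headline_records):
        """100 draws at sigma = 0.1 Da: at least 95 confirmed."""
        rec = headline_records[1591.9]
        ions = crosslinked_by_ions(rec.species)
        rng = np.random.default_rng(2024)
        confirmed = 0
        for _ in range(100):
            mzs = np.array([i.mz for i in ions]) + rng.normal(0, 0.1, len(ions))
            res = confirm_sequence(_msms(mzs, rec.mh), rec, TOL)
            confirmed += res.confirmed
        assert confirmed >= 95

    def test_no_peak_double_counted(self, headline_records):
        """One experimental peak never serves as evidence for two ions."""
        rec = headline_records[1591.9]
        ions = crosslinked_by_ions(rec.species)
        unique_mzs = sorted({round(i.mz, 6) for i in ions})
        res = confirm_sequence(_msms(unique_mzs, rec.mh), rec, TOL)
        observed = [m.observed_mz for m in res.matched_ions]
        assert len(observed) == len(set(observed))
        assert len(observed) <= len(unique_mzs)

    def test_tolerance_monotonicity(self, headline_records):
        rec = headline_records[1835.9]
        ions = crosslinked_by_ions(rec.species)
        rng = np.random.default_rng(5)
        mzs = np.array([i.mz for i in ions]) + rng.normal(0, 0.2, len(ions))
        pl = _msms(mzs, rec.mh)
        counts = [
            len(greedy_assign(ions, pl, tol)) for tol in (0.1, 0.2, 0.4, 0.8, 1.2)
        ]
        assert counts == sorted(counts)


class TestDisambiguate:
    def test_companion_present_calls_lal(self, model_db):
        ms = _ms([1835.93, 1869.92])
        hits = match_ms(ms, model_db, TOL)
        lal_hit = next(
            h for h in hits if h.record.link == "lysinoalanine" and round(h.record.mh, 1) == 1869.9
        )
        assert disambiguate(ms, lal_hit, TOL) == "LAL"

    def test_companion_absent_stays_ambiguous(self, model_db):
        ms = _ms([1869.92])
        hits = match_ms(ms, model_db, TOL)
        for h in hits:
            if round(h.record.mh, 1) == 1869.9 and h.record.link in (
                "lysinoalanine",
                "lanthionine",
            ):
                assert disambiguate(ms, h, TOL) == "ambiguous"

    def test_non_isobaric_hit_passthrough(self, model_db):
        ms = _ms([1901.89])
        hit = next(
            h for h in match_ms(ms, model_db, TOL) if h.record.link == "disulfide"
        )
        assert disambiguate(ms, hit, TOL) == "n/a"

    def test_no_companion_and_no_diagnostic_is_lanthionine_consistent(self, model_db):
        ms = _ms([1869.92])
        hits = match_ms(ms, model_db, TOL)
        lal_hit = next(h for h in hits if h.record.link == "lysinoalanine")
        empty_msms = _msms([300.0, 400.0], lal_hit.record.mh)
        assert disambiguate(ms, lal_hit, TOL, msms=empty_msms) == "lanthionine-consistent"


class TestDetectDiagnostic:
    def test_printed_observed_ions_match_within_0p18(self, model_db):
        rec = next(
            r
            for r in model_db
            if r.kind == "crosslink" and round(r.mh, 1) == 1835.9
        )
        msms = _msms([906.631, 930.465], rec.mh)
        evidence = detect_diagnostic(msms, rec, TOL)
        assert {m.ion.ion_class for m in evidence} == {"diag_i", "diag_ii"}
        assert max(abs(m.delta) for m in evidence) <= 0.18

    def test_empty_spectrum_gives_empty_evidence(self, model_db):
        rec = next(
            r
            for r in model_db
            if r.kind == "crosslink" and round(r.mh, 1) == 1835.9
        )
        assert detect_diagnostic(_msms([300.0], rec.mh), rec, TOL) == []

    def test_1256_fragment_ii_printed_delta(self, model_db):
        rec = next(
            r
            for r in model_db
            if r.kind == "crosslink"
            and round(r.mh, 1) == 1256.8
            and "*S*" in r.annotation
        )
        msms = _msms([687.556], rec.mh)
        evidence = detect_diagnostic(msms, rec, TOL)
        ii = next(m for m in evidence if m.ion.ion_class == "diag_ii")
        assert round(abs(ii.delta), 3) == 0.088


def _result(rec, confirmed, ph, days, rep):
    return IdentificationResult(
        record=rec,
        precursor=None,
        confirmed=confirmed,
        condition=Condition(pH=ph, days=days, replicate_id=rep),
    )


class TestReplicateFilter:
    def test_both_replicates_qualify(self, headline_records):
        rec = headline_records[1901.9]
        res = replicate_filter(
            [_result(rec, True, 12, 1, "1"), _result(rec, True, 12, 1, "2")]
        )
        assert len(res) == 2
        assert all(r.replicate_status == "duplicated" for r in res)

    def test_single_replicate_excluded(self, headline_records):
        rec = headline_records[1901.9]
        other = headline_records[1591.9]
        res = replicate_filter(
            [
                _result(rec, True, 12, 1, "1"),
                _result(other, True, 12, 1, "1"),
                _result(other, True, 12, 1, "2"),
            ]
        )
        assert {r.record.annotation for r in res} == {other.annotation}

    def test_replicate_order_symmetric(self, headline_records):
        rec = headline_records[1901.9]
        a = [_result(rec, True, 12, 1, "1"), _result(rec, True, 12, 1, "2")]
        fwd = replicate_filter(a)
        rev = replicate_filter(list(reversed(a)))
        assert [(r.record.annotation, r.condition.replicate_id) for r in fwd] == [
            (r.record.annotation, r.condition.replicate_id) for r in rev
        ]
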