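"""Theoretical fragment-ion generation: b/y, intact-bridge, diagnostic
pair, disulfide triplet, companion satellite, site localizers."""

import pytest

from lalms.chem import (
    H2O,
    H2S,
    PROTON,
    S,
    ChemError,
    CrosslinkSpecies,
    PeptideSpec,
    apply_modifications,
    crosslink_mass,
    mz,
    peptide_mass,
)
from lalms.fragments import (
    by_ions,
    companion_dha_mz,
    crosslinked_by_ions,
    diagnostic_pair,
    disulfide_triplet,
    site_localizing_ions,
)


class TestByIons:
    def test_count_is_2n_minus_2(self, lkdecfr):
        ions = by_ions(lkdecfr)
        assert len(ions) == 2 * (len(lkdecfr.sequence) - 1)

    @pytest.mark.parametrize("fixture", ["llklf", "lkdecfr", "llslr_mod"])
    def test_complementary_pairs_sum_to_constant(self, fixture, request):
        """b_k + y_(n-k) = precursor neutral mass + 2 protons, for all k."""
        p = request.getfixturevalue(fixture)
        ions = {i.annotation: i.mz for i in by_ions(p)}
        n = len(p.sequence)
        expected = peptide_mass(p) + 2 * PROTON
        for k in range(1, n):
            assert ions[f"b{k}"] + ions[f"y{n - k}"] == pytest.approx(
                expected, abs=1e-9
            )

    def test_modifications_ride_with_their_residue(self, llslr_mod):
        """The arginine modification shifts only fragments containing R."""
        plain = {i.annotation: i.mz for i in by_ions(llslr_mod)}
        dha = apply_modifications(llslr_mod, [(2, "dha_from_ser")])
        shifted = {i.annotation: i.mz for i in by_ions(dha)}
        assert shifted["b2"] == pytest.approx(plain["b2"], abs=1e-9)  # LL only
        assert shifted["b3"] == pytest.approx(plain["b3"] - H2O, abs=1e-9)
        assert shifted["y1"] == pytest.approx(plain["y1"], abs=1e-9)

    def test_single_residue_raises(self):
        with pytest.raises(ChemError):
            by_ions(PeptideSpec("K"))


class TestCrosslinkedByIons:
    def test_total_count(self, lal_1256):
        ions = crosslinked_by_ions(lal_1256)
        la = len(lal_1256.peptide_a.sequence)
        lb = len(lal_1256.peptide_b.sequence)
        assert len(ions) == 2 * (la - 1) + 2 * (lb - 1)

    def test_fragments_without_bridge_site_are_plain(self, lal_1256):
        ions = {i.annotation: i for i in crosslinked_by_ions(lal_1256)}
        plain_b = {i.annotation: i.mz for i in by_ions(lal_1256.peptide_b)}
        # acceptor LLKLF bridges at K (index 2): y1, y2 are plain
        assert not ions["b:y1"].crosslinked
        assert ions["b:y1"].mz == pytest.approx(plain_b["y1"], abs=1e-9)
        assert ions["b:y3+P"].crosslinked

    def test_bridge_fragments_carry_partner_plus_link_delta(self, lal_1256):
        ions = {i.annotation: i.mz for i in crosslinked_by_ions(lal_1256)}
        plain = {i.annotation: i.mz for i in by_ions(lal_1256.peptide_b)}
        partner = peptide_mass(lal_1256.chain_with_spares("a"))
        assert ions["b:y3+P"] == pytest.approx(
            plain["y3"] + partner - H2O, abs=1e-9
        )

    def test_all_mz_below_precursor_plus_2(self, lal_1835, lal_1256):
        for s in (lal_1835, lal_1256):
            limit = mz(crosslink_mass(s)) + 2.0
            for ion in crosslinked_by_ions(s):
                assert 0 < ion.mz <= limit


class TestDiagnosticPair:
    def test_gly_substitution_reproduces_printed_deviation_1835(self, lal_1835):
        cands = diagnostic_pair(lal_1835)["i"]
        canonical = [c for c in cands if c.variant == "even_electron"][0]
        assert round(abs(906.631 - canonical.mz), 3) == 0.163

    def test_fragment_ii_m_plus_ch2_reproduces_printed_deviation_1256(self, lal_1256):
        cands = diagnostic_pair(lal_1256)["ii"]
        m_ch2 = [c for c in cands if c.variant == "plus_CH2"][0]
        assert round(abs(687.556 - m_ch2.mz), 3) == 0.088

    def test_fragment_i_deviation_1256(self, lal_1256):
        """Printed 0.390 for the 571.772 ion; the proton convention gives
        0.3906, i.e. agreement within 1 mDa of the printed rounding."""
        cands = diagnostic_pair(lal_1256)["i"]
        dev = min(abs(571.772 - c.mz) for c in cands)
        assert abs(dev - 0.390) <= 1e-3

    def test_both_1835_ions_within_0p18(self, lal_1835):
        pair = diagnostic_pair(lal_1835)
        for observed, klass in ((906.631, "i"), (930.465, "ii")):
            dev = min(abs(observed - c.mz) for c in pair[klass])
            assert dev <= 0.18

    def test_non_lal_species_raises(self, lkdecfr):
        s = CrosslinkSpecies(lkdecfr, lkdecfr, "disulfide", 4, 4)
        with pytest.raises(ChemError):
            diagnostic_pair(s)

    def test_pair_mass_conservation(self, model_db):
        """Best candidate pairing of i + ii stays within 2.1 Da of the
        precursor neutral mass for every enumerated LAL species."""
        lal_records = [
            r for r in model_db if r.kind == "crosslink" and r.link == "lysinoalanine"
        ]
        assert lal_records
        for rec in lal_records:
            pair = diagnostic_pair(rec.species)
            precursor = crosslink_mass(rec.species)
            i_neutral = next(
                c.mz for c in pair["i"] if c.variant == "even_electron"
            ) - PROTON
            ii_neutral = next(c.mz for c in pair["ii"] if c.variant == "plus_CH2")
            # slack covers the H-transfer variant bookkeeping
            assert abs(i_neutral + ii_neutral - precursor) <= 2.1

    def test_every_variant_labeled(self, lal_1835):
        pair = diagnostic_pair(lal_1835)
        for ions in pair.values():
            assert all(ion.variant for ion in ions)
            assert len({ion.variant for ion in ions}) == len(ions)


class TestDisulfideTriplet:
    def test_homodimer_triplet_values(self, lkdecfr):
        s = CrosslinkSpecies(lkdecfr, lkdecfr, "disulfide", 4, 4)
        mzs = sorted({round(i.mz, 3) for i in disulfide_triplet(s)})
        center = peptide_mass(lkdecfr) + PROTON
        assert mzs == [
            round(center - H2S, 3),
            round(center, 3),
            round(center + S, 3),
        ]
        assert mzs[1] == pytest.approx(952.456, abs=1e-3)

    def test_span_is_constant(self, lkdecfr):
        s = CrosslinkSpecies(lkdecfr, lkdecfr, "disulfide", 4, 4)
        mzs = sorted(i.mz for i in disulfide_triplet(s) if i.chain == "a")
        assert mzs[2] - mzs[0] == pytest.approx(65.960, abs=1e-3)

    def test_homodimer_chains_coincide(self, lkdecfr):
        s = CrosslinkSpecies(lkdecfr, lkdecfr, "disulfide", 4, 4)
        assert len({round(i.mz, 6) for i in disulfide_triplet(s)}) == 3

    def test_non_disulfide_raises(self, lal_1835):
        with pytest.raises(ChemError):
            disulfide_triplet(lal_1835)


class TestCompanion:
    def test_lal_homopair_companion_is_spare_dha_species(self, lkdecfr, lal_1835):
        lal = CrosslinkSpecies(lkdecfr, lkdecfr, "lysinoalanine", 4, 1)
        comp = companion_dha_mz(lal)
        assert comp == pytest.approx(mz(crosslink_mass(lal)) - H2S, abs=1e-9)
        assert comp == pytest.approx(mz(crosslink_mass(lal_1835)), abs=1e-6)

    def test_lanthionine_has_no_companion(self, lkdecfr):
        lan = CrosslinkSpecies(lkdecfr, lkdecfr, "lanthionine", 4, 4)
        assert companion_dha_mz(lan) is None

    def test_lal_without_spare_site_has_no_companion(self, lal_1256):
        # Ser donor consumed; no spare Cys and no free Ser remain on LLSLR/LLKLF
        assert companion_dha_mz(lal_1256) is None

    def test_spare_ser_gives_water_loss_companion(self):
        a = PeptideSpec("CSK")
        s = CrosslinkSpecies(a, a, "lysinoalanine", 0, 2)
        assert companion_dha_mz(s) == pytest.approx(
            mz(crosslink_mass(s)) - H2S, abs=1e-9
        )  # spare Cys outranks spare Ser

    def test_disulfide_returns_none(self, lkdecfr):
        s = CrosslinkSpecies(lkdecfr, lkdecfr, "disulfide", 4, 4)
        assert companion_dha_mz(s) is None


class TestSiteLocalizers:
    def test_ser_variant_has_discriminating_ions(self, lal_1256, llslr_mod, llklf):
        twin = CrosslinkSpecies(llslr_mod, llklf, "lysinoalanine", 4, 2)
        loc = site_localizing_ions(lal_1256, [twin])
        assert loc

    def test_identical_twins_give_empty_set(self, lal_1256):
        assert site_localizing_ions(lal_1256, [lal_1256]) == []

    def test_returned_ions_unique_to_one_twin(self, lal_1256, llslr_mod, llklf):
        twin = CrosslinkSpecies(llslr_mod, llklf, "lysinoalanine", 4, 2)
        own = {round(i.mz, 4) for i in crosslinked_by_ions(lal_1256)}
        other = {round(i.mz, 4) for i in crosslinked_by_ions(twin)}
        for ion in site_localizing_ions(lal_1256, [twin]):
            key = round(ion.mz, 4)
            assert key in own and key not in other
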