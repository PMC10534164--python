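import numpy as np
import pytest

from lalms.chem import CrosslinkSpecies, PeptideSpec, apply_modifications
from lalms.database import enumerate_species


@pytest.fixture(scope="session")
def llklf():
    return PeptideSpec("LLKLF", name="LLKLF", n_term="acetyl", c_term="amide")


@pytest.fixture(scope="session")
def lkdecfr():
    return PeptideSpec("LKDECFR", name="LKDECFR", n_term="acetyl", c_term="free_acid")


@pytest.fixture(scope="session")
def llslr_no2():
    return PeptideSpec(
        "LLSLR",
        name="LLSLR",
        n_term="acetyl",
        c_term="amide",
        side_protections=((4, "arg_NO2"),),
    )


@pytest.fixture(scope="session")
def llslr_mod(llslr_no2):
    """LLSLR with the treatment-induced arginine modification applied."""
    return apply_modifications(llslr_no2, [(4, "arg_deprotect_deltaOH")])


@pytest.fixture(scope="session")
def model_db(llslr_no2, llklf, lkdecfr):
    return enumerate_species([llslr_no2, llklf, lkdecfr])


@pytest.fixture(scope="session")
def lal_1835(lkdecfr):
    """LAL homopair of LKDECFR with the spare-Cys dehydroalanine."""
    acceptor = apply_modifications(lkdecfr, [(4, "dha_from_cys")])
    return CrosslinkSpecies(lkdecfr, acceptor, "lysinoalanine", 4, 1)


@pytest.fixture(scope="session")
def lal_1256(llslr_mod, llklf):
    """LAL between modified LLSLR (Ser donor) and LLKLF."""
    return CrosslinkSpecies(llslr_mod, llklf, "lysinoalanine", 2, 2)


@pytest.fixture(scope="session")
def headline_records(model_db):
    """One database record per printed crosslink m/z (LAL member of
    isobaric groups), keyed by the 1-decimal [M+H]+."""
    groups: dict[float, list] = {}
    for r in model_db:
        if r.kind == "crosslink" and round(r.mh, 1) in (
            1256.8,
            1591.9,
            1835.9,
            1869.9,
            1901.9,
        ):
            groups.setdefault(round(r.mh, 1), []).append(r)
    out = {}
    for key, recs in groups.items():
        # prefer the LAL record; for 1256.8 the Ser-site variant
        lal = [r for r in recs if r.link == "lysinoalanine"]
        if key == 1256.8:
            lal = [r for r in lal if "*S*" in r.annotation]
        out[key] = lal[0] if lal else recs[0]
    return out
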