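"""lalms: locating lysinoalanine, lanthionine and disulfide crosslinks in
MALDI-TOF/TOF peak lists of model peptides."""

from importlib import resources

from .chem import (
    CrosslinkSpecies,
    PeptideSpec,
    apply_modifications,
    crosslink_mass,
    mz,
    peptide_mass,
)
from .database import CandidateDatabase, enumerate_species, pair_count, query
from .fragments import (
    TheoreticalIon,
    by_ions,
    companion_dha_mz,
    crosslinked_by_ions,
    diagnostic_pair,
    disulfide_triplet,
    site_localizing_ions,
)
from .matching import (
    Condition,
    IdentificationResult,
    PeakList,
    Tolerances,
    confirm_sequence,
    detect_diagnostic,
    disambiguate,
    match_ms,
    replicate_filter,
)
from .msio import RunConfig, read_peaklist, read_peptides, write_peaklist, write_results
from .pipeline import identify_run
from .synth import SimulationPlan, simulate_ms, simulate_msms, simulate_series
from .trends import ConditionSeries, TrendReport, presence_matrix, tic_normalize, trend

__version__ = "0.1.0"


def model_peptides() -> list[PeptideSpec]:
    """The three shipped model peptides: Ac-LLSLR-NH2 (Arg NO2-protected),
    Ac-LLKLF-NH2 and Ac-LKDECFR (free acid)."""
    ref = resources.files(__name__).joinpath("data/peptides.txt")
    from .chem import PeptideSpec as _P

    blocks = [b for b in ref.read_text().split("[peptide]") if b.strip()]
    out = []
    for b in blocks:
        lines = [l for l in b.splitlines() if "=" in l and not l.strip().startswith("#")]
        if lines:
            out.append(_P.deserialize("\n".join(lines)))
    return out
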