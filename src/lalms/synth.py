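"""Ground-truthed synthetic MS and MS/MS spectra.

Emulates the features of MALDI peak lists that the identification workflow
relies on — planted precursor and fragment peaks with Gaussian m/z jitter,
uniform-random noise peaks, lognormal arbitrary-unit intensities, replicate
spectra and monotone condition profiles — without modeling ionization
efficiency, isotope envelopes or matrix clusters.  Every planted peak is
recorded in a manifest so recovery can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .database import SpeciesRecord
from .fragments import (
    by_ions,
    crosslinked_by_ions,
    diagnostic_pair,
    disulfide_triplet,
)
from .chem import CrosslinkSpecies
from .matching import Condition, PeakList
from .trends import ConditionSeries

__all__ = ["SimulationPlan", "simulate_ms", "simulate_msms", "simulate_series"]


@dataclass(frozen=True)
class SimulationPlan:
    """What to plant and how noisy to make it.

    ``species`` maps each database record to a base intensity (arbitrary
    units).  ``jitter_sigma`` is the Gaussian m/z error (Da, default a
    quarter of the MS tolerance); ``noise_fraction`` sets the number of
    uniform-random noise peaks relative to the planted count.  A seed is
    mandatory: all randomness flows from it.
    """

    species: tuple[tuple[SpeciesRecord, float], ...]
    seed: int
    jitter_sigma: float = 0.05
    noise_fraction: float = 0.2
    intensity_cv: float = 0.2  # lognormal spread of planted intensities
    window: tuple[float, float] = (700.0, 3000.0)

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be >= 0")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be >= 0")


def _intensity(rng: np.random.Generator, base: float, cv: float) -> float:
    if cv <= 0:
        return base
    sigma = np.sqrt(np.log(1 + cv**2))
    return float(base * rng.lognormal(-(sigma**2) / 2, sigma))


def _add_noise(
    rng: np.random.Generator,
    plan: SimulationPlan,
    n_planted: int,
    median_intensity: float,
) -> tuple[list[float], list[float]]:
    n_noise = int(round(plan.noise_fraction * n_planted))
    lo, hi = plan.window
    mzs = rng.uniform(lo, hi, n_noise).tolist()
    intens = [
        _intensity(rng, 0.2 * median_intensity, max(plan.intensity_cv, 0.1))
        for _ in range(n_noise)
    ]
    return mzs, intens


def simulate_ms(
    plan: SimulationPlan,
    condition: Condition | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PeakList, pd.DataFrame]:
    """One MS spectrum: a jittered [M+H]+ peak per planted species plus
    noise; the manifest maps every planted peak back to its species."""
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    condition = condition or Condition()
    mzs: list[float] = []
    intens: list[float] = []
    manifest_rows = []
    for rec, base in plan.species:
        lo, hi = plan.window
        if not lo <= rec.mh <= hi:
            warnings.warn(
                f"species {rec.annotation} [M+H]+ {rec.mh:.3f} outside window",
                stacklevel=2,
            )
        planted = rec.mh + rng.normal(0.0, plan.jitter_sigma) if plan.jitter_sigma else rec.mh
        inten = _intensity(rng, base, plan.intensity_cv)
        mzs.append(planted)
        intens.append(inten)
        manifest_rows.append(
            {
                "annotation": rec.annotation,
                "ion": "precursor",
                "theoretical_mz": rec.mh,
                "planted_mz": planted,
                "intensity": inten,
            }
        )
    median = float(np.median(intens)) if intens else 1.0
    nmz, nint = _add_noise(rng, plan, len(mzs), median)
    pl = PeakList(
        np.asarray(mzs + nmz), np.asarray(intens + nint), level="MS", condition=condition
    )
    return pl, pd.DataFrame(manifest_rows)


def simulate_msms(
    plan: SimulationPlan,
    record: SpeciesRecord,
    condition: Condition | None = None,
    rng: np.random.Generator | None = None,
    include_diagnostic: bool = True,
    diag_ii_variant: str = "plus_CH2",
    drop_by_ordinals: Sequence[str] = (),
) -> tuple[PeakList, pd.DataFrame]:
    """One MS/MS spectrum of a planted species.

    Plants the full backbone (plain + intact-bridge b/y) series, the
    diagnostic pair for lysinoalanine (one H-transfer variant per fragment,
    selectable), the triplet markers for disulfide, and noise.
    ``drop_by_ordinals`` removes named backbone ions (e.g. ``"a:b3"``) to
    construct under-confirmed spectra.
    """
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    condition = condition or Condition()
    species = record.species
    if isinstance(species, CrosslinkSpecies):
        ions = list(crosslinked_by_ions(species))
        if species.link == "lysinoalanine" and include_diagnostic:
            pair = diagnostic_pair(species)
            ions.append(pair["i"][0])  # canonical i
            ions.extend(ion for ion in pair["ii"] if ion.variant == diag_ii_variant)
        if species.link == "disulfide":
            ions.extend(disulfide_triplet(species))
    else:
        ions = list(by_ions(species))
    ions = [
        ion
        for ion in ions
        if ion.annotation.removesuffix("+P") not in drop_by_ordinals
    ]
    mzs, intens, manifest_rows = [], [], []
    for ion in ions:
        planted = ion.mz + rng.normal(0.0, plan.jitter_sigma) if plan.jitter_sigma else ion.mz
        inten = _intensity(rng, 100.0, plan.intensity_cv)
        mzs.append(planted)
        intens.append(inten)
        manifest_rows.append(
            {
                "annotation": record.annotation,
                "ion": ion.annotation,
                "theoretical_mz": ion.mz,
                "planted_mz": planted,
                "intensity": inten,
            }
        )
    n_noise = int(round(plan.noise_fraction * len(mzs)))
    noise_mz = rng.uniform(50.0, record.mh + 2.0, n_noise).tolist()
    noise_int = [_intensity(rng, 20.0, max(plan.intensity_cv, 0.1)) for _ in range(n_noise)]
    pl = PeakList(
        np.asarray(mzs + noise_mz),
        np.asarray(intens + noise_int),
        level="MSMS",
        precursor_mz=record.mh,
        condition=condition,
    )
    return pl, pd.DataFrame(manifest_rows)


def simulate_series(
    plan: SimulationPlan,
    axis: str,
    levels: Sequence[float],
    profiles: Mapping[str, Sequence[float]],
    n_replicates: int = 2,
) -> ConditionSeries:
    """Replicated MS spectra over a condition axis with per-species
    intensity multipliers.

    ``profiles`` maps species annotation to one multiplier per level; a
    multiplier of 0 omits the species at that level entirely (emulating a
    crosslink not formed under that condition).
    """
    if any(len(p) != len(levels) for p in profiles.values()):
        raise ValueError("each profile needs one multiplier per level")
    ss = np.random.SeedSequence(plan.seed)
    children = ss.spawn(len(levels) * n_replicates)
    peaklists: dict[float, tuple[PeakList, ...]] = {}
    for li, lvl in enumerate(levels):
        reps = []
        for ri in range(n_replicates):
            rng = np.random.default_rng(children[li * n_replicates + ri])
            scaled = tuple(
                (rec, base * profiles.get(rec.annotation, [1.0] * len(levels))[li])
                for rec, base in plan.species
                if profiles.get(rec.annotation, [1.0] * len(levels))[li] > 0
            )
            cond = Condition(
                pH=lvl if axis == "pH" else None,
                days=lvl if axis == "days" else None,
                replicate_id=str(ri + 1),
            )
            lvl_plan = SimulationPlan(
                species=scaled,
                seed=plan.seed,
                jitter_sigma=plan.jitter_sigma,
                noise_fraction=plan.noise_fraction,
                intensity_cv=plan.intensity_cv,
                window=plan.window,
            )
            pl, _ = simulate_ms(lvl_plan, condition=cond, rng=rng)
            reps.append(pl)
        peaklists[float(lvl)] = tuple(reps)
    return ConditionSeries(axis=axis, levels=tuple(float(l) for l in levels), peaklists=peaklists)
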