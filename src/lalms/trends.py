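"""TIC normalization and cross-condition trend analysis of crosslink peaks.

MALDI peak intensities are not quantitative and there is no internal
standard, so absolute amounts are never reported.  Spectra are normalized
to their total ion current (TIC) and only relative, within-spectrum
intensities are compared across a pH series or a heating-time series.  The
direction of a trend is summarized by the Spearman rank correlation between
condition level and the replicate-averaged normalized intensity of a
target peak — a deliberately rank-only statistic, since the underlying
intensities are ordinal at best.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matching import Condition, IdentificationResult, PeakList

__all__ = [
    "ConditionSeries",
    "TrendReport",
    "tic_normalize",
    "trend",
    "presence_matrix",
    "THREE_HOURS_DAYS",
]

#: 3 h heating encoded as a fraction of a day for axis ordering
THREE_HOURS_DAYS = 0.125


def tic_normalize(pl: PeakList) -> PeakList:
    """Divide every intensity by the total ion current; m/z unchanged.

    Idempotent and scale-invariant.  Raises on an all-zero spectrum.
    """
    total = float(np.sum(pl.intensity))
    if total <= 0:
        raise ValueError("cannot TIC-normalize a spectrum with zero total intensity")
    return replace(pl, intensity=pl.intensity / total)


@dataclass(frozen=True)
class ConditionSeries:
    """Replicated peak lists over an ordered condition axis (pH or days)."""

    axis: str  # "pH" | "days"
    levels: tuple[float, ...]
    peaklists: Mapping[float, tuple[PeakList, ...]]  # level -> replicates

    def __post_init__(self) -> None:
        if self.axis not in ("pH", "days"):
            raise ValueError(f"unknown axis {self.axis!r}")
        if len(self.levels) < 2:
            raise ValueError("a condition series needs at least 2 levels")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")
        for lvl in self.levels:
            if lvl not in self.peaklists or not self.peaklists[lvl]:
                raise ValueError(f"no peak lists for level {lvl}")


@dataclass(frozen=True)
class TrendReport:
    """Normalized intensities per target/level/replicate plus a direction
    statistic (Spearman rho of replicate means vs level) per target."""

    axis: str
    table: pd.DataFrame  # columns: target, level, replicate, raw, normalized
    direction: Mapping[str, float]


def trend(
    series: ConditionSeries,
    targets: Mapping[str, float],
    tol: float = 0.2,
) -> TrendReport:
    """Extract normalized target intensities across a series and rank-correlate.

    For each target m/z the nearest peak within ``tol`` is taken per
    replicate spectrum (0 if absent).  Direction is the Spearman rho of the
    replicate-averaged normalized intensity against the level values; a
    target absent everywhere gets rho = 0.
    """
    rows = []
    for lvl in series.levels:
        for ri, pl in enumerate(series.peaklists[lvl]):
            npl = tic_normalize(pl)
            for name, target_mz in targets.items():
                raw_peak = pl.nearest_peak(target_mz, tol)
                norm_peak = npl.nearest_peak(target_mz, tol)
                rows.append(
                    {
                        "target": name,
                        "level": lvl,
                        "replicate": ri,
                        "raw": raw_peak[1] if raw_peak else 0.0,
                        "normalized": norm_peak[1] if norm_peak else 0.0,
                    }
                )
    table = pd.DataFrame(rows)
    direction: dict[str, float] = {}
    for name in targets:
        sub = table[table["target"] == name]
        means = sub.groupby("level")["normalized"].mean()
        levels = np.asarray(means.index, dtype=float)
        values = means.to_numpy()
        if np.allclose(values, values[0]):
            rho = 0.0
        else:
            rho = float(stats.spearmanr(levels, values).statistic)
        direction[name] = rho
    return TrendReport(axis=series.axis, table=table, direction=direction)


def presence_matrix(
    qualified: Iterable[IdentificationResult],
    ph_levels: Sequence[float] | None = None,
    key=None,
) -> pd.DataFrame:
    """Detection grid: per (species, pH) the sorted days where the species
    qualified under the duplicate rule.

    Expects results that have already passed :func:`replicate_filter`; one
    row per species (labeled by annotation, or by ``key(result)`` if given
    — e.g. the rounded precursor m/z to merge isobaric twins), one column
    per pH, cells are tuples of days (empty tuple = never detected).
    """
    qualified = list(qualified)
    key = key or (lambda r: r.record.annotation)
    cells: dict[tuple[str, float], set[float]] = {}
    phs: set[float] = set(ph_levels or ())
    species: list[str] = []
    for r in qualified:
        ph, days = r.condition.pH, r.condition.days
        if ph is None or days is None:
            continue
        phs.add(ph)
        label = key(r)
        if label not in species:
            species.append(label)
        cells.setdefault((label, ph), set()).add(days)
    cols = sorted(phs)
    data = {
        ph: [tuple(sorted(cells.get((sp, ph), ()))) for sp in sorted(species)]
        for ph in cols
    }
    return pd.DataFrame(data, index=sorted(species))
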