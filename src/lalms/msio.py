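"""Peak-list and results I/O.

MS spectra are exchanged as two-column ASCII (m/z, intensity) — the least
common denominator of vendor exports — and MS/MS spectra as MGF, the
minimal standard format that carries a precursor m/z (PEPMASS).  Results
are written as TSV.  Peptide definitions are plain-text key-value blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf

from .chem import PeptideSpec
from .matching import Condition, IdentificationResult, PeakList

__all__ = [
    "RunConfig",
    "PeakListFormatError",
    "read_peaklist",
    "write_peaklist",
    "read_peptides",
    "write_peptides",
    "write_results",
]


class PeakListFormatError(ValueError):
    """Malformed peak-list input (reported with line number where possible)."""


@dataclass(frozen=True)
class RunConfig:
    """Run-wide parameters with the instrument-method defaults."""

    ms_tol: float = 0.2
    msms_tol: float = 0.8
    mz_window: tuple[float, float] = (700.0, 3000.0)
    max_spare_mods: int = 2
    adducts: tuple[str, ...] = ("proton",)
    out_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mz_window
        if not lo < hi:
            raise ValueError("m/z window min must be < max")
        if self.ms_tol <= 0 or self.msms_tol <= 0:
            raise ValueError("tolerances must be positive")


def _apply_window(
    mzs: np.ndarray, intens: np.ndarray, window: tuple[float, float] | None, origin: str
) -> tuple[np.ndarray, np.ndarray]:
    if window is None:
        return mzs, intens
    lo, hi = window
    keep = (mzs >= lo) & (mzs <= hi)
    if not keep.all():
        warnings.warn(
            f"{origin}: {int((~keep).sum())} peak(s) outside acquisition window "
            f"[{lo}, {hi}] dropped",
            stacklevel=3,
        )
    return mzs[keep], intens[keep]


def read_peaklist(
    path: str | Path,
    dialect: str = "two_column_text",
    condition: Condition | None = None,
    window: tuple[float, float] | None = None,
) -> PeakList | list[PeakList]:
    """Read a centroided peak list.

    ``two_column_text`` yields one MS-level :class:`PeakList`; ``mgf``
    yields a list of MSMS-level peak lists (one per spectrum, PEPMASS ->
    precursor m/z).  Blank lines and ``#`` comments are tolerated in the
    text dialect.  Out-of-window peaks are dropped with a warning.
    """
    path = Path(path)
    condition = condition or Condition()
    if dialect == "two_column_text":
        mzs, intens = [], []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise PeakListFormatError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError as exc:
                raise PeakListFormatError(f"{path}:{lineno}: {exc}") from exc
        mz_arr, int_arr = _apply_window(
            np.asarray(mzs, float), np.asarray(intens, float), window, str(path)
        )
        return PeakList(mz_arr, int_arr, level="MS", condition=condition)
    if dialect == "mgf":
        out: list[PeakList] = []
        with mgf.read(str(path)) as reader:
            for spec in reader:
                params = spec.get("params", {})
                pepmass = params.get("pepmass")
                if pepmass is None:
                    raise PeakListFormatError(
                        f"{path}: MGF spectrum without PEPMASS"
                    )
                out.append(
                    PeakList(
                        np.asarray(spec["m/z array"], float),
                        np.asarray(spec["intensity array"], float),
                        level="MSMS",
                        precursor_mz=float(pepmass[0]),
                        condition=condition,
                    )
                )
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    """Write in the dialect matching the peak list's level (text or MGF)."""
    path = Path(path)
    if pl.level == "MS":
        lines = [f"{m:.6f}\t{i:.6f}" for m, i in zip(pl.mz, pl.intensity)]
        path.write_text("\n".join(lines) + "\n")
    else:
        spectrum = {
            "m/z array": pl.mz,
            "intensity array": pl.intensity,
            "params": {
                "pepmass": pl.precursor_mz,
                "charge": "1+",
                "title": pl.condition.sample_name or "spectrum",
            },
        }
        mgf.write([spectrum], str(path), file_mode="w")


def read_peptides(path: str | Path) -> list[PeptideSpec]:
    """Parse a plain-text peptide definition file (blocks split on blank
    lines or ``[peptide]`` headers, 1-based site indices)."""
    text = Path(path).read_text()
    blocks: list[list[str]] = [[]]
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("[peptide]"):
            if blocks[-1]:
                blocks.append([])
            continue
        if stripped.startswith("#"):
            continue
        blocks[-1].append(line)
    return [PeptideSpec.deserialize("\n".join(b)) for b in blocks if b]


def write_peptides(peptides: Sequence[PeptideSpec], path: str | Path) -> None:
    Path(path).write_text(
        "\n\n".join("[peptide]\n" + p.serialize() for p in peptides) + "\n"
    )


RESULT_COLUMNS = (
    "crosslink",
    "annotation",
    "theoretical_mz",
    "observed_mz",
    "delta",
    "matched_by_ions",
    "required_by_ions",
    "confirmed",
    "disambiguation",
    "site_verdict",
    "replicate_status",
    "pH",
    "days",
    "replicate",
)


def write_results(results: Iterable[IdentificationResult], path: str | Path) -> None:
    """Write identification results as TSV with a fixed column order.

    1-based sites in annotations; masses to 3 decimals; deterministic row
    order follows the input order.
    """
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in results:
        obs = r.precursor.observed_mz if r.precursor else float("nan")
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    r.record.link or "linear",
                    r.record.annotation,
                    f"{r.record.mh:.3f}",
                    f"{obs:.3f}",
                    f"{obs - r.record.mh:.3f}",
                    r.by_ion_count,
                    r.required_by_count,
                    r.confirmed,
                    r.disambiguation,
                    r.site_verdict,
                    r.replicate_status,
                    r.condition.pH if r.condition.pH is not None else "-",
                    r.condition.days if r.condition.days is not None else "-",
                    r.condition.replicate_id,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
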