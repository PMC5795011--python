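"""MS2 spectrum container and Mascot generic format (MGF) I/O.

Parsing and writing go through pyteomics.mgf; this module pins the dialect
used throughout the package: TITLE, PEPMASS (first token = m/z), CHARGE
("3+"), optional RTINSECONDS, and "mz intensity" peak lines. A spectrum
without a CHARGE line is kept with ``charge=None`` so downstream code can
decide what to do with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from pyteomics import mgf as _mgf

__all__ = ["Spectrum", "MGFError", "read_mgf", "write_mgf"]


class MGFError(ValueError):
    """An MGF file could not be parsed."""


@dataclass
class Spectrum:
    """One MS2 spectrum; peaks are an (n, 2) array sorted ascending by m/z."""

    spectrum_id: str
    precursor_mz: float
    charge: int | None
    peaks: np.ndarray
    retention_time: float | None = None

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]
        if not self.precursor_mz > 0:
            raise ValueError("precursor_mz must be positive")
        if len(self.peaks) and (self.peaks[:, 1] < 0).any():
            raise ValueError("negative peak intensity")

    @property
    def mz(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks[:, 1]


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read every BEGIN IONS/END IONS block of an MGF file."""
    spectra: list[Spectrum] = []
    try:
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for block in reader:
                params = block["params"]
                title = str(params.get("title", f"spectrum_{len(spectra) + 1}"))
                try:
                    pepmass = float(params["pepmass"][0])
                except (KeyError, TypeError, IndexError) as exc:
                    raise MGFError(
                        f"{path}: block {title!r} has no parseable PEPMASS"
                    ) from exc
                charge_field = params.get("charge")
                charge = int(charge_field[0]) if charge_field else None
                rt = params.get("rtinseconds")
                peaks = np.column_stack(
                    [block["m/z array"], block["intensity array"]]
                ) if len(block["m/z array"]) else np.empty((0, 2))
                spectra.append(
                    Spectrum(
                        spectrum_id=title,
                        precursor_mz=pepmass,
                        charge=charge,
                        peaks=peaks,
                        retention_time=float(rt) if rt is not None else None,
                    )
                )
    except MGFError:
        raise
    except Exception as exc:
        raise MGFError(f"{path}: malformed MGF ({exc})") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra in the same dialect read_mgf expects.

    m/z values carry six decimals so a write/read round trip preserves every
    peak to well under 1e-5 Da.
    """
    blocks = []
    for s in spectra:
        params: dict = {"title": s.spectrum_id, "pepmass": s.precursor_mz}
        if s.charge is not None:
            params["charge"] = s.charge
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time
        blocks.append(
            {
                "params": params,
                "m/z array": s.mz,
                "intensity array": s.intensity,
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        _mgf.write(blocks, fh, fragment_format="{:.6f} {:.6f}")
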