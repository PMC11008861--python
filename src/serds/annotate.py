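"""Peak detection and molecular assignment for purified Raman spectra.

The assignment library lists the fingerprint bands of soft and mineralised
tissue: collagen backbone and phenylalanine modes, nucleic-acid C-N
stretches, carotenoid chains, the amide I/II/III protein bands and the
lipid/protein C-H deformation region.  Peaks are detected by prominence
(fraction of the spectrum maximum) and matched to point entries within a
tolerance or to band entries by containment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


@dataclass(frozen=True)
class LibraryEntry:
    """One assignment: a point position or a band (low==high for points)."""

    low_cm1: float
    high_cm1: float
    assignment: str

    def __post_init__(self) -> None:
        if not (200.0 <= self.low_cm1 <= self.high_cm1 <= 2000.0):
            raise ValueError("entry must lie within [200, 2000] cm^-1 with low <= high")

    @property
    def is_band(self) -> bool:
        return self.high_cm1 > self.low_cm1

    @property
    def center(self) -> float:
        return 0.5 * (self.low_cm1 + self.high_cm1)


def _point(shift: float, text: str) -> LibraryEntry:
    return LibraryEntry(shift, shift, text)


#: Fingerprint-band assignments for near-infrared tissue Raman spectra.
DEFAULT_LIBRARY: tuple[LibraryEntry, ...] = (
    _point(937.5, "Proline, hydroxyproline, C-C stretching of collagen backbone"),
    _point(1004, "Phenylalanine (of collagen)"),
    _point(1038, "Phenylalanine (of collagen)"),
    _point(1073, "Proline (collagen), glucose, triglycerides, C-C (lipid)"),
    _point(1095, "DNA, C-N stretching"),
    _point(1126, "C-N stretching"),
    _point(1160, "C-C stretching of the carotenoid polyene chain"),
    LibraryEntry(1200, 1320, "Amide III region"),
    _point(1339, "CH2 deformation (protein, A and G of DNA/RNA), nucleic acid"),
    _point(1378, "CH3 in-phase deformation (T, A, G of DNA)"),
    LibraryEntry(1440, 1470, "C-H deformation from CH2/CH3 of lipid and protein"),
    _point(1532, "Amide II, carotenoid peak"),
    LibraryEntry(1600, 1670, "Amide I region"),
)

#: Phosphate nu1 marker of mineralised tissue; diagnostic for bone.
PHOSPHATE_SHIFT_CM1 = 960.0


@dataclass
class PeakCall:
    apex_cm1: float
    apex_intensity: float
    prominence: float
    assignment: str | None = None
    distance_cm1: float | None = None

    def __post_init__(self) -> None:
        if self.prominence <= 0:
            raise ValueError("prominence must be positive")
        if self.assignment is not None and (self.distance_cm1 or 0.0) < 0:
            raise ValueError("assignment distance must be nonnegative")


def detect_peaks(spectrum, min_prominence: float = 0.05) -> list[PeakCall]:
    """Local maxima with prominence >= min_prominence * max(spectrum).

    Returns calls sorted by shift.  ``spectrum`` is a PurifiedSpectrum.
    """
    values = np.asarray(spectrum.values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 bins")
    if not np.all(np.isfinite(values)):
        raise ValueError("spectrum contains non-finite values")
    vmax = values.max()
    if vmax <= 0:
        return []
    idx, props = find_peaks(values, prominence=min_prominence * vmax)
    return [PeakCall(apex_cm1=float(spectrum.shift_cm1[i]),
                     apex_intensity=float(values[i]),
                     prominence=float(p))
            for i, p in zip(idx, props["prominences"])]


def assign_peaks(calls: list[PeakCall],
                 library: tuple[LibraryEntry, ...] = DEFAULT_LIBRARY,
                 tolerance_cm1: float = 8.0) -> list[PeakCall]:
    """Annotate peak calls against the library.

    Point entries match within ``tolerance_cm1``; band entries match by
    containment (distance 0).  The nearest matching entry wins ties;
    unmatched calls stay unassigned.
    """
    if tolerance_cm1 <= 0:
        raise ValueError("tolerance must be positive")
    if not library:
        raise ValueError("assignment library is empty")
    out = []
    for call in calls:
        best: tuple[float, LibraryEntry] | None = None
        for entry in library:
            if entry.is_band:
                if entry.low_cm1 <= call.apex_cm1 <= entry.high_cm1:
                    d = 0.0
                else:
                    continue
            else:
                d = abs(call.apex_cm1 - entry.low_cm1)
                if d > tolerance_cm1:
                    continue
            if best is None or d < best[0]:
                best = (d, entry)
        out.append(PeakCall(apex_cm1=call.apex_cm1,
                            apex_intensity=call.apex_intensity,
                            prominence=call.prominence,
                            assignment=best[1].assignment if best else None,
                            distance_cm1=best[0] if best else None))
    return out


def annotation_table(calls: list[PeakCall]) -> pd.DataFrame:
    """Annotated calls as a delimited-table-ready DataFrame."""
    return pd.DataFrame({
        "shift_cm1": [c.apex_cm1 for c in calls],
        "intensity": [c.apex_intensity for c in calls],
        "prominence": [c.prominence for c in calls],
        "assignment": [c.assignment or "" for c in calls],
        "distance_cm1": [np.nan if c.distance_cm1 is None else c.distance_cm1
                         for c in calls],
    })
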