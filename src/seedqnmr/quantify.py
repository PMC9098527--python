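"""Internal-standard qNMR quantification of assigned metabolite signals.

The core mass equation converts the ratio of an analyte signal integral to
the TSP reference integral into an absolute analyte mass:

    m_X = m_ST · (A_X / A_ST) · (MW_X / MW_ST) · (N_ST / N_X)

where m_ST is the internal-standard mass (0.7 mg TSP in the emulated
protocol), A are integral areas, MW molecular weights and N the numbers of
protons behind each integrated signal (9 for TSP). Concentrations are
expressed as mg analyte per g of the 500 mg extracted sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .processing import Peak, calibrate_to_tsp, pick_peaks
from .signature import SignatureLibrary, load_signature_library
from .simulate import Spectrum

__all__ = [
    "QuantificationInput",
    "ConcentrationProfile",
    "QuantificationError",
    "qnmr_mass",
    "quantify_spectrum",
    "DEFAULT_ASSIGNMENT_TOL_PPM",
    "DEFAULT_PRESENCE_MIN_SNR",
]

logger = logging.getLogger(__name__)

#: Half-width of the shift-matching window for peak→metabolite assignment.
DEFAULT_ASSIGNMENT_TOL_PPM = 0.02

#: A metabolite is called present when its assigned quantification signal
#: has SNR at or above this value (operational detection limit).
DEFAULT_PRESENCE_MIN_SNR = 3.0


class QuantificationError(RuntimeError):
    """Raised when the TSP reference signal cannot be found."""


@dataclass(frozen=True)
class QuantificationInput:
    """Inputs to the qNMR mass equation for one analyte signal."""

    A_X: float
    A_ST: float
    MW_X: float
    MW_ST: float
    N_X: int
    N_ST: int
    m_ST: float

    def __post_init__(self) -> None:
        if self.A_X < 0:
            raise ValueError("A_X must be >= 0")
        if self.A_ST <= 0:
            raise ValueError("A_ST must be > 0")
        if self.MW_X <= 0 or self.MW_ST <= 0:
            raise ValueError("molecular weights must be > 0")
        if self.N_X < 1 or self.N_ST < 1:
            raise ValueError("proton counts must be >= 1")
        if self.m_ST <= 0:
            raise ValueError("m_ST must be > 0")


def qnmr_mass(q: QuantificationInput) -> float:
    """Analyte mass in mg from the internal-standard ratio equation.

    Linear in ``A_X``; the identity case (equal areas, weights and proton
    counts) returns ``m_ST`` exactly.
    """
    return (
        q.m_ST * (q.A_X / q.A_ST) * (q.MW_X / q.MW_ST) * (q.N_ST / q.N_X)
    )


@dataclass(frozen=True)
class ConcentrationProfile:
    """Per-metabolite concentrations (mg/g) and presence calls for one line."""

    line_id: str
    conc_mg_per_g: dict[str, float]
    present: dict[str, bool]
    assignments: dict[str, list[Peak]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, c in self.conc_mg_per_g.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}")

    def n_present(self) -> int:
        return sum(self.present.values())

    def to_frame(self, library: SignatureLibrary | None = None) -> pd.DataFrame:
        """One row per metabolite: line_id, metabolite, class, mg/g, present."""
        library = library or load_signature_library()
        rows = []
        for e in library.entries:
            rows.append(
                {
                    "line_id": self.line_id,
                    "metabolite": e.name,
                    "metabolite_class": e.metabolite_class,
                    "conc_mg_per_g": self.conc_mg_per_g.get(e.name, 0.0),
                    "present": bool(self.present.get(e.name, False)),
                }
            )
        return pd.DataFrame(rows)


def _assign_peaks(
    peaks: list[Peak],
    library: SignatureLibrary,
    tol_ppm: float,
) -> dict[str, list[Peak]]:
    """Assign each picked peak to the nearest quantification shift in range.

    A peak with two or more candidate metabolites within tolerance goes to
    the nearest shift; the conflict is logged. Peaks matching nothing are
    dropped (they may be corroborating signals or noise).
    """
    assigned: dict[str, list[Peak]] = {}
    for peak in peaks:
        hits = [
            (abs(e.quant_shift_ppm - peak.apex_ppm), e.name)
            for e in library.entries
            if abs(e.quant_shift_ppm - peak.apex_ppm) <= tol_ppm
        ]
        if not hits:
            continue
        hits.sort()
        if len(hits) > 1:
            logger.debug(
                "ambiguous peak at %.4f ppm: candidates %s; assigned to %s",
                peak.apex_ppm,
                [h[1] for h in hits],
                hits[0][1],
            )
        assigned.setdefault(hits[0][1], []).append(peak)
    return assigned


def quantify_spectrum(
    spectrum: Spectrum,
    library: SignatureLibrary | None = None,
    tol_ppm: float = DEFAULT_ASSIGNMENT_TOL_PPM,
    sample_mass_mg: float = 500.0,
    m_ST_mg: float = 0.7,
    min_snr: float = DEFAULT_PRESENCE_MIN_SNR,
) -> ConcentrationProfile:
    """Quantify every assignable metabolite in a calibrated spectrum.

    The spectrum is (re-)calibrated to TSP (idempotent), peaks are picked,
    the TSP integral ``A_ST`` is taken as the summed area of peaks within
    ``tol_ppm`` of 0 ppm, and each library entry matched by a picked peak
    within ``tol_ppm`` of its quantification shift receives a mass from
    :func:`qnmr_mass` (areas of all peaks assigned to that shift are summed,
    which collects the components of split multiplets). Concentration is
    ``m_X / (sample_mass_mg/1000)`` mg/g. Presence requires an assigned
    signal with SNR ≥ ``min_snr``. A global intensity rescaling of the
    spectrum leaves the result unchanged (ratio-based).

    Raises
    ------
    QuantificationError
        If no TSP reference peak is found.
    """
    library = library or load_signature_library()
    spectrum = calibrate_to_tsp(spectrum)
    peaks = pick_peaks(spectrum, min_snr=min_snr)

    tsp_peaks = [p for p in peaks if abs(p.apex_ppm) <= tol_ppm]
    a_st = sum(p.area for p in tsp_peaks)
    if not tsp_peaks or a_st <= 0:
        raise QuantificationError("no TSP reference peak within tolerance of 0 ppm")
    rest = [p for p in peaks if abs(p.apex_ppm) > tol_ppm]
    assigned = _assign_peaks(rest, library, tol_ppm)

    tsp = library.internal_standard
    line_id = str(spectrum.meta.get("line_id", ""))
    conc: dict[str, float] = {}
    present: dict[str, bool] = {}
    for entry in library.entries:
        hits = assigned.get(entry.name, [])
        if not hits:
            conc[entry.name] = 0.0
            present[entry.name] = False
            continue
        a_x = sum(p.area for p in hits)
        mass = qnmr_mass(
            QuantificationInput(
                A_X=a_x,
                A_ST=a_st,
                MW_X=entry.molecular_weight,
                MW_ST=tsp.molecular_weight,
                N_X=entry.n_protons,
                N_ST=tsp.n_protons,
                m_ST=m_ST_mg,
            )
        )
        conc[entry.name] = mass / (sample_mass_mg / 1000.0)
        present[entry.name] = max(p.snr for p in hits) >= min_snr
    return ConcentrationProfile(
        line_id=line_id, conc_mg_per_g=conc, present=present, assignments=assigned
    )
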