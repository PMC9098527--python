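"""Forward simulation of 1D ¹H-NMR spectra of seed extracts.

Generates spectra with known ground-truth composition so that every
downstream stage (calibration, peak picking, internal-standard
quantification, panel profiling, chemometrics) can be validated without
instrument data. The forward model inverts the qNMR mass equation: each
present metabolite receives a multiplet at its quantification shift whose
total area is

    A_X = A_ST · (m_X / m_ST) · (MW_ST / MW_X) · (N_X / N_ST)

so that quantification against the TSP reference singlet (area ``A_ST`` at
0.00 ppm) recovers the simulated mass ``m_X`` exactly in the noise-free
limit. Lineshapes are Lorentzian; multiplets use a single scalar coupling
constant J = 7 Hz.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .signature import MetaboliteSignature, SignatureLibrary, load_signature_library

__all__ = [
    "AcquisitionParams",
    "LineGroundTruth",
    "Spectrum",
    "simulate_spectrum",
    "simulate_panel",
    "simulate_two_regime_panel",
    "DEFAULT_PRESENCE_PROB",
    "DEFAULT_CONC_LOGNORMAL",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_panel",
    "read_panel",
]

#: Scalar coupling constant applied to all doublets/triplets, Hz.
J_COUPLING_HZ = 7.0

#: Reference integral assigned to the TSP singlet (arbitrary intensity units;
#: quantification is ratio-based so the value is immaterial).
TSP_REFERENCE_AREA = 100.0

#: Lineshape evaluation half-window, ppm. A Lorentzian truncated at
#: ±0.15 ppm (±90 Hz at 600 MHz) retains ≥ 99.5% of its area at the default
#: 1.2 Hz linewidth; the same truncation applies to analytes and reference,
#: so integral ratios are unaffected.
LINESHAPE_WINDOW_PPM = 0.15

#: Corroborating (non-quantification) signals are rendered only when at
#: least this far from every other library signal, so that peak assignment
#: by nearest quantification shift stays well-posed. Equals twice the
#: default 0.02-ppm assignment tolerance.
SECONDARY_MIN_SEPARATION_PPM = 0.04

# Per-class Bernoulli presence probabilities for a germplasm panel. Chosen to
# emulate the study panel: amino acids and the major sugars are nearly
# universal, vitamins the most variable; expected per-line total ≈ 35 of 45
# with a 5th–95th percentile span of roughly 29–41.
DEFAULT_PRESENCE_PROB = {
    "amino_acid": 0.85,
    "sugar": 0.85,
    "flavonoid_polyphenol": 0.70,
    "organic_phenolic_steroid_sugar_alcohol": 0.75,
    "vitamin": 0.60,
}

# Per-class lognormal (mu, sigma) of the analyte mass in mg per 500 mg
# extracted sample. With the default presence probabilities these yield
# per-line grand totals of roughly 60–140 mg/g, i.e. the tens-of-mg/g scale
# reported for legume seed panels.
DEFAULT_CONC_LOGNORMAL = {
    "amino_acid": (math.log(1.1), 0.6),
    "sugar": (math.log(2.2), 0.6),
    "flavonoid_polyphenol": (math.log(1.2), 0.6),
    "organic_phenolic_steroid_sugar_alcohol": (math.log(1.2), 0.6),
    "vitamin": (math.log(0.45), 0.6),
}


@dataclass(frozen=True)
class AcquisitionParams:
    """Synthetic acquisition settings.

    ``linewidth_hz`` is the Lorentzian full width at half maximum (0.6 Hz
    default — a well-shimmed 600 MHz small-molecule spectrum; it also keeps
    the four-component rendered multiplets baseline-resolved at the fixed
    J = 7 Hz). The default axis (32768 points over −0.5..9.5 ppm) resolves
    0.04-ppm buckets with ≥ 130 points each. ``noise_sd`` is the additive
    Gaussian noise standard deviation in the same intensity units as the
    TSP reference peak (height ≈ 640 units at the default linewidth);
    ``baseline_amplitude`` scales a slowly varying random cubic baseline.
    """

    ppm_min: float = -0.5
    ppm_max: float = 9.5
    n_points: int = 32768
    linewidth_hz: float = 0.6
    spectrometer_mhz: float = 600.0
    noise_sd: float = 0.5
    baseline_amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.ppm_min >= self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth_hz must be > 0")
        if self.spectrometer_mhz <= 0:
            raise ValueError("spectrometer_mhz must be > 0")

    @property
    def linewidth_ppm(self) -> float:
        return self.linewidth_hz / self.spectrometer_mhz

    def axis(self) -> np.ndarray:
        return np.linspace(self.ppm_min, self.ppm_max, self.n_points)

    def to_dict(self) -> dict:
        return {
            "ppm_min": self.ppm_min,
            "ppm_max": self.ppm_max,
            "n_points": self.n_points,
            "linewidth_hz": self.linewidth_hz,
            "spectrometer_mhz": self.spectrometer_mhz,
            "noise_sd": self.noise_sd,
            "baseline_amplitude": self.baseline_amplitude,
        }


@dataclass(frozen=True)
class LineGroundTruth:
    """True composition of one simulated germplasm line.

    ``masses_mg`` maps metabolite name to analyte mass m_X in mg contained in
    the 500 mg extracted sample; ``tsp_mass_mg`` is the internal-standard
    mass m_ST (0.7 mg in the emulated protocol).
    """

    line_id: str
    masses_mg: dict[str, float]
    tsp_mass_mg: float = 0.7

    def __post_init__(self) -> None:
        if self.tsp_mass_mg <= 0:
            raise ValueError("tsp_mass_mg must be > 0")
        for name, m in self.masses_mg.items():
            if m < 0:
                raise ValueError(f"negative mass for {name}")

    def conc_mg_per_g(self, sample_mass_mg: float = 500.0) -> dict[str, float]:
        """True concentrations in mg analyte per g sample."""
        return {
            k: v / (sample_mass_mg / 1000.0) for k, v in self.masses_mg.items()
        }

    def to_dict(self) -> dict:
        return {
            "line_id": self.line_id,
            "masses_mg": dict(self.masses_mg),
            "tsp_mass_mg": self.tsp_mass_mg,
        }


@dataclass(frozen=True)
class Spectrum:
    """A 1D spectrum: strictly monotone ppm axis, intensities, metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", intensity)
        if ppm.ndim != 1 or ppm.shape != intensity.shape:
            raise ValueError("ppm and intensity must be equal-length 1D arrays")
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")

    @property
    def step(self) -> float:
        return float(abs(self.ppm[1] - self.ppm[0]))

    def with_axis(self, ppm: np.ndarray) -> "Spectrum":
        return Spectrum(ppm=ppm, intensity=self.intensity, meta=dict(self.meta))


@lru_cache(maxsize=1)
def _default_library() -> SignatureLibrary:
    return load_signature_library()


def _multiplet_components(
    center_ppm: float, multiplicity: str, j_ppm: float
) -> list[tuple[float, float]]:
    """(position, area fraction) of each sub-peak of a multiplet.

    Doublets/triplets use binomial intensity ratios split by J; 'dd' and 'm'
    are rendered as four equal sub-peaks spanning 2J — a deterministic
    stand-in for patterns whose true couplings are not modelled.
    """
    if multiplicity == "s":
        return [(center_ppm, 1.0)]
    if multiplicity == "d":
        return [(center_ppm - j_ppm / 2, 0.5), (center_ppm + j_ppm / 2, 0.5)]
    if multiplicity == "t":
        return [
            (center_ppm - j_ppm, 0.25),
            (center_ppm, 0.5),
            (center_ppm + j_ppm, 0.25),
        ]
    if multiplicity in ("dd", "m"):
        return [
            (center_ppm + f * j_ppm, 0.25) for f in (-1.0, -1.0 / 3, 1.0 / 3, 1.0)
        ]
    raise ValueError(f"unknown multiplicity {multiplicity!r}")


_rendered_cache: dict[int, dict[str, list[tuple[float, str]]]] = {}


def rendered_shifts(library: SignatureLibrary) -> dict[str, list[tuple[float, str]]]:
    """Per metabolite, the (shift, multiplicity) signals the simulator renders.

    The quantification shift is always rendered. A corroborating shift is
    rendered only when it lies at least
    :data:`SECONDARY_MIN_SEPARATION_PPM` from every other library signal
    (including the TSP reference at 0 ppm); closer duplicates are skipped so
    the rendered spectrum stays consistent with one-signal-per-metabolite
    assignment.
    """
    key = id(library)
    if key in _rendered_cache:
        return _rendered_cache[key]
    positions = [s for e in library.entries for s in e.shifts_ppm] + [
        library.internal_standard.quant_shift_ppm
    ]
    out: dict[str, list[tuple[float, str]]] = {}
    for e in library.entries:
        sigs: list[tuple[float, str]] = []
        for s, m in zip(e.shifts_ppm, e.multiplicities):
            if s == e.quant_shift_ppm:
                sigs.append((s, m))
                continue
            others = [p for p in positions if p != s]
            if min(abs(s - p) for p in others) >= SECONDARY_MIN_SEPARATION_PPM - 1e-12:
                sigs.append((s, m))
        out[e.name] = sigs
    _rendered_cache[key] = out
    return out


def _add_lorentzian(
    intensity: np.ndarray,
    ppm: np.ndarray,
    center: float,
    area: float,
    fwhm_ppm: float,
) -> None:
    """Add a Lorentzian of given integral in place (windowed evaluation)."""
    lo = np.searchsorted(ppm, center - LINESHAPE_WINDOW_PPM)
    hi = np.searchsorted(ppm, center + LINESHAPE_WINDOW_PPM)
    if hi <= lo:
        return
    x = ppm[lo:hi]
    hwhm = fwhm_ppm / 2.0
    shape = area * (hwhm / math.pi) / ((x - center) ** 2 + hwhm**2)
    # subtract the edge level so the windowed evaluation is continuous
    # (a hard truncation step would seed artificial local maxima)
    edge = area * (hwhm / math.pi) / (LINESHAPE_WINDOW_PPM**2 + hwhm**2)
    intensity[lo:hi] += np.maximum(shape - edge, 0.0)


def analyte_area(
    entry: MetaboliteSignature,
    mass_mg: float,
    tsp: MetaboliteSignature,
    tsp_mass_mg: float,
    tsp_area: float = TSP_REFERENCE_AREA,
) -> float:
    """Forward area of a metabolite's quantification signal.

    Inverts the qNMR mass equation:
    ``A_X = A_ST · (m_X/m_ST) · (MW_ST/MW_X) · (N_X/N_ST)``.
    """
    return (
        tsp_area
        * (mass_mg / tsp_mass_mg)
        * (tsp.molecular_weight / entry.molecular_weight)
        * (entry.n_protons / tsp.n_protons)
    )


def simulate_spectrum(
    truth: LineGroundTruth,
    params: AcquisitionParams | None = None,
    seed: int = 0,
    library: SignatureLibrary | None = None,
) -> Spectrum:
    """Render one line's spectrum from its ground-truth composition.

    Every metabolite with positive mass gets its rendered multiplets (see
    :func:`rendered_shifts`); the TSP reference singlet at 0.00 ppm carries
    area :data:`TSP_REFERENCE_AREA`. Gaussian noise and a random slow cubic
    baseline are added from ``seed``; identical inputs and seed give a
    bit-identical spectrum.

    Raises
    ------
    KeyError
        If a metabolite in ``truth`` is not in the signature library.
    """
    params = params or AcquisitionParams()
    library = library or _default_library()
    ppm = params.axis()
    intensity = np.zeros_like(ppm)
    j_ppm = J_COUPLING_HZ / params.spectrometer_mhz
    lw_ppm = params.linewidth_ppm
    tsp = library.internal_standard
    signals = rendered_shifts(library)

    # reference singlet
    _add_lorentzian(intensity, ppm, tsp.quant_shift_ppm, TSP_REFERENCE_AREA, lw_ppm)

    for name, mass in truth.masses_mg.items():
        if mass == 0:
            continue
        entry = library.get(name)  # KeyError if unknown
        area = analyte_area(entry, mass, tsp, truth.tsp_mass_mg)
        for shift, mult in signals[entry.name]:
            for pos, frac in _multiplet_components(shift, mult, j_ppm):
                _add_lorentzian(intensity, ppm, pos, area * frac, lw_ppm)

    rng = np.random.default_rng(seed)
    if params.baseline_amplitude > 0:
        u = (ppm - params.ppm_min) / (params.ppm_max - params.ppm_min)
        coef = rng.uniform(-1.0, 1.0, size=4)
        intensity += params.baseline_amplitude * np.polyval(coef, u)
    else:
        rng.uniform(-1.0, 1.0, size=4)  # keep the stream aligned
    if params.noise_sd > 0:
        intensity += rng.normal(0.0, params.noise_sd, size=ppm.size)

    meta = {
        "line_id": truth.line_id,
        "seed": int(seed),
        "tsp_mass_mg": truth.tsp_mass_mg,
        "acquisition": params.to_dict(),
    }
    return Spectrum(ppm=ppm, intensity=intensity, meta=meta)


def _draw_truth(
    rng: np.random.Generator,
    line_id: str,
    library: SignatureLibrary,
    presence_prob: dict[str, float],
    conc_lognormal: dict[str, tuple[float, float]],
    tsp_mass_mg: float,
) -> LineGroundTruth:
    masses: dict[str, float] = {}
    for entry in library.entries:
        p = presence_prob[entry.metabolite_class]
        present = rng.random() < p
        mu, sigma = conc_lognormal[entry.metabolite_class]
        mass = float(rng.lognormal(mu, sigma))  # drawn regardless, keeps
        # the random stream per-entry aligned across presence patterns
        if present:
            masses[entry.name] = mass
    return LineGroundTruth(line_id=line_id, masses_mg=masses, tsp_mass_mg=tsp_mass_mg)


def simulate_panel(
    n_lines: int,
    presence_prob: dict[str, float] | float | None = None,
    conc_lognormal: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    params: AcquisitionParams | None = None,
    library: SignatureLibrary | None = None,
    line_prefix: str = "SIM",
    tsp_mass_mg: float = 0.7,
) -> tuple[list[Spectrum], list[LineGroundTruth]]:
    """Simulate a germplasm panel of ``n_lines`` spectra with ground truth.

    Each line carries a random subset of the 45 metabolites (per-class
    Bernoulli presence) at per-class lognormal masses. ``presence_prob`` may
    be a single float applied to all classes. Reproducible under ``seed``.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    library = library or _default_library()
    if presence_prob is None:
        presence_prob = dict(DEFAULT_PRESENCE_PROB)
    elif isinstance(presence_prob, (int, float)):
        presence_prob = {c: float(presence_prob) for c in DEFAULT_PRESENCE_PROB}
    for cls, p in presence_prob.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"presence probability for {cls} outside [0, 1]")
    conc_lognormal = conc_lognormal or DEFAULT_CONC_LOGNORMAL

    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_lines)))
    spectra: list[Spectrum] = []
    truths: list[LineGroundTruth] = []
    for i in range(n_lines):
        line_id = f"{line_prefix}-{i + 1:0{width}d}"
        truth = _draw_truth(
            rng, line_id, library, presence_prob, conc_lognormal, tsp_mass_mg
        )
        line_seed = int(rng.integers(0, 2**31 - 1))
        spectra.append(simulate_spectrum(truth, params, seed=line_seed, library=library))
        truths.append(truth)
    return spectra, truths


def simulate_two_regime_panel(
    n_per_regime: int,
    seed: int = 0,
    enrichment: float = 4.0,
    sigma: float = 0.25,
    presence_prob: float = 0.9,
    params: AcquisitionParams | None = None,
    library: SignatureLibrary | None = None,
) -> tuple[list[Spectrum], list[LineGroundTruth], list[str]]:
    """Panel with two concentration regimes (two class-mean vectors).

    The regimes model two abundance chemotypes over a shared metabolite
    roster: regime ``B`` lines carry ``enrichment``-fold higher class-median
    concentrations than regime ``A``, both with within-regime lognormal
    spread ``sigma`` and a common per-metabolite presence probability
    ``presence_prob``. Returns spectra, truths and the regime label
    ('A' or 'B') per line, order A then B.
    """
    base = {c: (mu, sigma) for c, (mu, _) in DEFAULT_CONC_LOGNORMAL.items()}
    rich = {c: (mu + math.log(enrichment), sigma) for c, (mu, _) in base.items()}
    spec_a, truth_a = simulate_panel(
        n_per_regime, presence_prob=presence_prob, conc_lognormal=base,
        seed=seed, params=params, library=library, line_prefix="A",
    )
    spec_b, truth_b = simulate_panel(
        n_per_regime, presence_prob=presence_prob, conc_lognormal=rich,
        seed=seed + 1, params=params, library=library, line_prefix="B",
    )
    labels = ["A"] * n_per_regime + ["B"] * n_per_regime
    return spec_a + spec_b, truth_a + truth_b, labels


# ---------------------------------------------------------------------------
# plain-text exchange formats

def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column CSV (ppm, intensity); metadata in a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity})
    df.to_csv(path, index=False, float_format="%.8g")
    if spectrum.meta:
        path.with_suffix(".meta.json").write_text(
            json.dumps(spectrum.meta, indent=1, sort_keys=True)
        )


def read_spectrum_csv(path: str | Path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Spectrum(
        ppm=df["ppm"].to_numpy(), intensity=df["intensity"].to_numpy(), meta=meta
    )


def write_panel(
    spectra: list[Spectrum],
    truths: list[LineGroundTruth],
    out_dir: str | Path,
) -> Path:
    """Write spectra CSVs, ground-truth JSON sidecars and a panel manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    line_ids = []
    for spec, truth in zip(spectra, truths):
        stem = truth.line_id
        write_spectrum_csv(spec, out / f"{stem}.csv")
        (out / f"{stem}.truth.json").write_text(
            json.dumps(truth.to_dict(), indent=1, sort_keys=True)
        )
        line_ids.append(stem)
    manifest = out / "panel_manifest.json"
    manifest.write_text(json.dumps({"line_ids": line_ids}, indent=1))
    return manifest


def read_panel(
    panel_dir: str | Path,
) -> tuple[list[Spectrum], list[LineGroundTruth | None]]:
    """Read a panel written by :func:`write_panel` (truths optional)."""
    panel_dir = Path(panel_dir)
    manifest = json.loads((panel_dir / "panel_manifest.json").read_text())
    spectra, truths = [], []
    for line_id in manifest["line_ids"]:
        spectra.append(read_spectrum_csv(panel_dir / f"{line_id}.csv"))
        tpath = panel_dir / f"{line_id}.truth.json"
        if tpath.exists():
            d = json.loads(tpath.read_text())
            truths.append(
                LineGroundTruth(
                    line_id=d["line_id"],
                    masses_mg=d["masses_mg"],
                    tsp_mass_mg=d["tsp_mass_mg"],
                )
            )
        else:
            truths.append(None)
    return spectra, truths
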