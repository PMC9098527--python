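"""Panel-level summaries: metabolite counts, class totals, chemo-markers,
and micro-Kjeldahl crude protein.

A germplasm panel is represented as a lines × metabolites concentration
matrix (mg/g, 0 = absent) with an optional per-line crude-protein column.
Chemo-markers are reported as presence frequencies with a thresholded
near-universal list; the interpretation of "differential" markers is left
to the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .quantify import ConcentrationProfile
from .signature import SignatureLibrary, load_signature_library

__all__ = [
    "PanelMatrix",
    "KjeldahlParams",
    "metabolite_counts",
    "class_totals",
    "chemomarker_report",
    "kjeldahl_protein",
    "panel_summary",
]

#: mg of nitrogen per mL of 1 N acid × 100 (micro-Kjeldahl titre constant).
KJELDAHL_N_FACTOR = 1.4007

#: Default nitrogen→crude-protein conversion factor for seed storage protein.
PROTEIN_CONVERSION_FACTOR = 6.25


@dataclass(frozen=True)
class PanelMatrix:
    """Lines × metabolites concentration table plus optional protein %.

    ``conc`` is a DataFrame indexed by line_id with metabolite columns
    (mg/g; 0 means absent). ``protein_pct`` is an optional Series aligned to
    the same index.
    """

    conc: pd.DataFrame
    protein_pct: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.conc.to_numpy() < 0).any():
            raise ValueError("concentrations must be >= 0")
        if self.protein_pct is not None and not self.protein_pct.index.equals(
            self.conc.index
        ):
            raise ValueError("protein_pct index must match conc index")

    @property
    def line_ids(self) -> list[str]:
        return list(self.conc.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.conc.columns)

    @property
    def presence(self) -> pd.DataFrame:
        return self.conc > 0

    @classmethod
    def from_profiles(
        cls,
        profiles: list[ConcentrationProfile],
        library: SignatureLibrary | None = None,
        protein_pct: dict[str, float] | None = None,
    ) -> "PanelMatrix":
        library = library or load_signature_library()
        names = library.names()
        rows = {}
        for p in profiles:
            rows[p.line_id] = [
                p.conc_mg_per_g.get(n, 0.0) if p.present.get(n, False) else 0.0
                for n in names
            ]
        conc = pd.DataFrame.from_dict(rows, orient="index", columns=names)
        conc.index.name = "line_id"
        prot = None
        if protein_pct is not None:
            prot = pd.Series(protein_pct, name="protein_pct").reindex(conc.index)
        return cls(conc=conc, protein_pct=prot)

    def to_csv(self, path: str | Path) -> None:
        df = self.conc.copy()
        if self.protein_pct is not None:
            df["protein_pct"] = self.protein_pct
        df.to_csv(path, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PanelMatrix":
        df = pd.read_csv(path, index_col="line_id")
        prot = None
        if "protein_pct" in df.columns:
            prot = df.pop("protein_pct")
        return cls(conc=df, protein_pct=prot)


def _class_of(library: SignatureLibrary) -> dict[str, str]:
    return {e.name: e.metabolite_class for e in library.entries}


def metabolite_counts(
    profile: ConcentrationProfile,
    library: SignatureLibrary | None = None,
) -> dict[str, int]:
    """Present-metabolite counts per class plus ``total`` (≤ 45)."""
    library = library or load_signature_library()
    classes = _class_of(library)
    counts: dict[str, int] = {c: 0 for c in set(classes.values())}
    for name, is_present in profile.present.items():
        if name not in classes:
            raise KeyError(f"unknown metabolite {name!r}")
        if is_present:
            counts[classes[name]] += 1
    counts["total"] = sum(counts.values())
    return counts


def class_totals(
    profile: ConcentrationProfile,
    library: SignatureLibrary | None = None,
) -> dict[str, float]:
    """Per-class mg/g sums of present metabolites plus the grand ``total``."""
    library = library or load_signature_library()
    classes = _class_of(library)
    totals: dict[str, float] = {c: 0.0 for c in set(classes.values())}
    for name, conc in profile.conc_mg_per_g.items():
        if name not in classes:
            raise KeyError(f"unknown metabolite {name!r}")
        if profile.present.get(name, False):
            totals[classes[name]] += conc
    totals["total"] = sum(totals.values())
    return totals


def chemomarker_report(
    panel: PanelMatrix,
    min_fraction: float = 0.95,
) -> pd.DataFrame:
    """Presence frequency per metabolite with a near-universal flag.

    Frequency is the fraction of panel lines in which the metabolite is
    present; metabolites with frequency ≥ ``min_fraction`` are flagged
    ``near_universal`` (at the 0.95 default this means "present in all lines
    except a handful", the pattern of panel-wide markers). Rows are ordered
    by decreasing frequency, ties broken by name; the ordering — and the
    frequencies — are invariant to line order.
    """
    if len(panel.line_ids) == 0:
        raise ValueError("empty panel")
    freq = panel.presence.mean(axis=0)
    df = pd.DataFrame(
        {"metabolite": freq.index, "frequency": freq.to_numpy()}
    )
    df["near_universal"] = df["frequency"] >= min_fraction
    df = df.sort_values(
        ["frequency", "metabolite"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


@dataclass(frozen=True)
class KjeldahlParams:
    """Micro-Kjeldahl titration inputs for crude-protein estimation.

    ``V_sample``/``V_blank`` are HCl titre volumes in mL, ``normality`` the
    acid normality (0.1 N in the emulated protocol), ``sample_mass_g`` the
    digested seed mass (0.2–0.25 g typical), ``conversion_factor`` the
    nitrogen→protein factor (6.25 for seed storage protein) and ``n_factor``
    the standard micro-Kjeldahl constant 1.4007 (mg N per mL of 1 N acid,
    scaled ×100 to express %N directly).
    """

    V_sample: float
    V_blank: float = 0.0
    normality: float = 0.1
    sample_mass_g: float = 0.25
    conversion_factor: float = PROTEIN_CONVERSION_FACTOR
    n_factor: float = KJELDAHL_N_FACTOR

    def __post_init__(self) -> None:
        if self.V_blank < 0 or self.V_sample < self.V_blank:
            raise ValueError("require V_sample >= V_blank >= 0")
        if self.normality <= 0:
            raise ValueError("normality must be > 0")
        if self.sample_mass_g <= 0:
            raise ValueError("sample_mass_g must be > 0")
        if self.conversion_factor <= 0:
            raise ValueError("conversion_factor must be > 0")


def kjeldahl_protein(p: KjeldahlParams) -> float:
    """Crude protein % from titre volumes.

    %N = (V_sample − V_blank) · normality · 1.4007 / sample_mass_g;
    protein % = %N · conversion_factor. Monotone increasing in ``V_sample``
    and decreasing in ``sample_mass_g``; equal titres give 0.
    """
    pct_n = (p.V_sample - p.V_blank) * p.normality * p.n_factor / p.sample_mass_g
    return pct_n * p.conversion_factor


def panel_summary(
    panel: PanelMatrix,
    library: SignatureLibrary | None = None,
) -> pd.DataFrame:
    """Per-line summary: class counts, total count, grand total mg/g, protein %."""
    library = library or load_signature_library()
    classes = _class_of(library)
    class_names = sorted(set(classes.values()))
    pres = panel.presence
    rows = []
    for line_id in panel.line_ids:
        row: dict[str, object] = {"line_id": line_id}
        for c in class_names:
            cols = [m for m in panel.metabolites if classes.get(m) == c]
            row[f"n_{c}"] = int(pres.loc[line_id, cols].sum())
            row[f"mg_per_g_{c}"] = float(panel.conc.loc[line_id, cols].sum())
        row["n_total"] = int(pres.loc[line_id].sum())
        row["mg_per_g_total"] = float(panel.conc.loc[line_id].sum())
        if panel.protein_pct is not None:
            row["protein_pct"] = float(panel.protein_pct.loc[line_id])
        rows.append(row)
    return pd.DataFrame(rows)
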