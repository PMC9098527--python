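"""Chemical-shift signature library for horsegram seed ¹H-NMR profiling.

The library packages the 45-metabolite chemical signature established for
*Macrotyloma uniflorum* (horsegram) seed extracts: per metabolite, the
characteristic ¹H chemical shifts and multiplicities, the single signal used
for quantification, the number of protons behind that signal, and the
molecular weight — everything the internal-standard qNMR mass equation needs.
The internal standard (TSP, 9 equivalent trimethylsilyl protons at 0.00 ppm)
ships as a separate record.

The data live in ``data/signature_table.tsv`` (documented columns, one row
per metabolite) so that values such as molecular weights can be audited or
swapped without touching code.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
import pandas as pd

__all__ = [
    "MetaboliteSignature",
    "SignatureLibrary",
    "SignatureValidationError",
    "load_signature_library",
    "match_shift",
    "classify_region",
    "METABOLITE_CLASSES",
    "EXPECTED_CLASS_TALLIES",
]

#: Metabolite classes used throughout the package.
METABOLITE_CLASSES = (
    "amino_acid",
    "sugar",
    "flavonoid_polyphenol",
    "organic_phenolic_steroid_sugar_alcohol",
    "vitamin",
    "miscellaneous",
)

#: Class composition of the 45-metabolite signature (abstract tally of the
#: underlying study: 17 amino acids, 7 flavonoids/polyphenols, 10 organic
#: acids/phenolic acids/sugar alcohols/steroids, 7 sugars, 4 vitamins).
EXPECTED_CLASS_TALLIES = {
    "amino_acid": 17,
    "flavonoid_polyphenol": 7,
    "organic_phenolic_steroid_sugar_alcohol": 10,
    "sugar": 7,
    "vitamin": 4,
}

_VALID_MULTIPLICITIES = frozenset({"s", "d", "dd", "t", "m"})

#: δ regions of a 1D seed-extract spectrum and their dominant compound types.
REGIONS = (
    ("aliphatic_0_3", 0.0, 3.0),   # fatty acids, amino acids, lipids, steroids
    ("sugar_3_6", 3.0, 6.0),       # sugars, polyols
    ("aromatic_6_9", 6.0, 9.0),    # ketones, aldehydes, vitamins, polyphenols
)


class SignatureValidationError(ValueError):
    """Raised when the packaged signature table violates a library invariant."""


@dataclass(frozen=True)
class MetaboliteSignature:
    """One metabolite's ¹H signature and quantification constants.

    Parameters
    ----------
    name : str
        Unique snake_case identifier.
    metabolite_class : str
        One of :data:`METABOLITE_CLASSES` (or ``internal_standard`` for TSP).
    shifts_ppm : tuple of float
        Characteristic chemical shifts δ in ppm; the first is the
        quantification signal, the rest corroborate presence.
    multiplicities : tuple of str
        Splitting pattern per shift (s, d, dd, t, m).
    quant_shift_ppm : float
        The shift whose integral enters the qNMR mass equation.
    n_protons : int
        Protons contributing to the quantification signal.
    molecular_weight : float
        Average molecular weight in g/mol.
    source : str
        Provenance of the shift assignment (``text``, ``supplement``,
        ``inferred``).
    note : str
        Assigned proton group and caveats.
    """

    name: str
    metabolite_class: str
    shifts_ppm: tuple[float, ...]
    multiplicities: tuple[str, ...]
    quant_shift_ppm: float
    n_protons: int
    molecular_weight: float
    source: str = "text"
    note: str = ""

    def __post_init__(self) -> None:
        if not self.shifts_ppm:
            raise SignatureValidationError(f"{self.name}: no shifts")
        if len(self.shifts_ppm) != len(self.multiplicities):
            raise SignatureValidationError(
                f"{self.name}: shifts and multiplicities differ in length"
            )
        for m in self.multiplicities:
            if m not in _VALID_MULTIPLICITIES:
                raise SignatureValidationError(
                    f"{self.name}: invalid multiplicity {m!r}"
                )
        for s in self.shifts_ppm:
            if not 0.0 <= s <= 9.5:
                raise SignatureValidationError(
                    f"{self.name}: shift {s} outside [0.0, 9.5] ppm"
                )
        if self.quant_shift_ppm not in self.shifts_ppm:
            raise SignatureValidationError(
                f"{self.name}: quant shift {self.quant_shift_ppm} not among shifts"
            )
        if self.n_protons < 1:
            raise SignatureValidationError(f"{self.name}: n_protons < 1")
        if self.molecular_weight <= 0:
            raise SignatureValidationError(f"{self.name}: non-positive MW")


def _normalize_name(name: str) -> str:
    """Map user-facing spellings ('α-glucose', 'D-Xylose') onto table ids."""
    s = name.strip().lower()
    s = s.replace("α", "alpha").replace("β", "beta")
    s = unicodedata.normalize("NFKD", s)
    s = "".join(c if c.isalnum() else "_" for c in s)
    while "__" in s:
        s = s.replace("__", "_")
    return s.strip("_")


@dataclass(frozen=True)
class SignatureLibrary:
    """The full 45-entry signature plus the TSP internal-standard record."""

    entries: tuple[MetaboliteSignature, ...]
    internal_standard: MetaboliteSignature
    _index: dict[str, MetaboliteSignature] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise SignatureValidationError("duplicate metabolite names")
        if len(self.entries) != 45:
            raise SignatureValidationError(
                f"expected 45 metabolites, found {len(self.entries)}"
            )
        tallies = self.class_tallies()
        if tallies != EXPECTED_CLASS_TALLIES:
            raise SignatureValidationError(
                f"class tallies {tallies} != expected {EXPECTED_CLASS_TALLIES}"
            )
        object.__setattr__(
            self, "_index", {_normalize_name(e.name): e for e in self.entries}
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def class_tallies(self) -> dict[str, int]:
        tallies: dict[str, int] = {}
        for e in self.entries:
            tallies[e.metabolite_class] = tallies.get(e.metabolite_class, 0) + 1
        return tallies

    def get(self, name: str) -> MetaboliteSignature:
        """Look an entry up by name.

        Exact (normalized) matches win; otherwise a unique substring match is
        accepted, so ``get("sucrose")`` resolves to ``sucrose_stachyose`` and
        ``get("α-glucose")`` to ``alpha_glucose``.
        """
        key = _normalize_name(name)
        if key in self._index:
            return self._index[key]
        hits = [e for k, e in self._index.items() if key in k]
        if len(hits) == 1:
            return hits[0]
        if not hits:
            raise KeyError(f"no signature entry matching {name!r}")
        raise KeyError(
            f"ambiguous name {name!r}: matches {[e.name for e in hits]}"
        )

    def __contains__(self, name: str) -> bool:
        try:
            self.get(name)
            return True
        except KeyError:
            return False

    def all_shifts(self) -> list[tuple[str, float, bool]]:
        """All (name, shift, is_quant_shift) triples, sorted by shift."""
        out = [
            (e.name, s, s == e.quant_shift_ppm)
            for e in self.entries
            for s in e.shifts_ppm
        ]
        return sorted(out, key=lambda t: (t[1], t[0]))


def _parse_row(row: pd.Series) -> MetaboliteSignature:
    shifts = tuple(float(x) for x in str(row["shifts_ppm"]).split(";"))
    mults = tuple(str(row["multiplicities"]).split(";"))
    note = row.get("note", "")
    return MetaboliteSignature(
        name=str(row["name"]),
        metabolite_class=str(row["metabolite_class"]),
        shifts_ppm=shifts,
        multiplicities=mults,
        quant_shift_ppm=float(row["quant_shift_ppm"]),
        n_protons=int(row["n_protons"]),
        molecular_weight=float(row["molecular_weight"]),
        source=str(row["source"]),
        note="" if pd.isna(note) else str(note),
    )


def load_signature_library(path: str | None = None) -> SignatureLibrary:
    """Load and validate the packaged signature table.

    Parameters
    ----------
    path : str, optional
        Alternative TSV with the documented column schema; by default the
        table shipped with the package is used.

    Returns
    -------
    SignatureLibrary
        Validated library: exactly 45 uniquely named entries with class
        tallies 17/7/10/7/4, plus the TSP internal-standard record.

    Raises
    ------
    SignatureValidationError
        If the table violates any library invariant; the message names the
        failing invariant.
    """
    if path is None:
        src = resources.files("seedqnmr.data").joinpath("signature_table.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")

    records = [_parse_row(row) for _, row in df.iterrows()]
    standards = [r for r in records if r.metabolite_class == "internal_standard"]
    entries = [r for r in records if r.metabolite_class != "internal_standard"]
    if len(standards) != 1:
        raise SignatureValidationError(
            f"expected exactly one internal_standard row, found {len(standards)}"
        )
    return SignatureLibrary(entries=tuple(entries), internal_standard=standards[0])


def match_shift(
    library: SignatureLibrary,
    observed_ppm: float,
    tolerance_ppm: float,
) -> list[tuple[MetaboliteSignature, float]]:
    """Rank library entries whose quantification shift lies near a δ value.

    Returns all entries with ``|quant_shift_ppm − observed_ppm| ≤
    tolerance_ppm`` as ``(entry, distance)`` pairs ordered by increasing
    distance, ties broken alphabetically by name. Empty list when nothing
    matches.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    hits = [
        (e, abs(e.quant_shift_ppm - observed_ppm))
        for e in library.entries
        if abs(e.quant_shift_ppm - observed_ppm) <= tolerance_ppm
    ]
    return sorted(hits, key=lambda t: (t[1], t[0].name))


def classify_region(ppm: float) -> str:
    """Assign a δ value to one of the three spectral regions.

    The spectrum splits into aliphatic [0, 3), sugar/polyol [3, 6) and
    aromatic [6, 9] regions (half-open intervals; the 9.0 endpoint belongs to
    the aromatic region), partitioning [0, 9].
    """
    if not 0.0 <= ppm <= 9.0:
        raise ValueError(f"ppm {ppm} outside the assignment range [0, 9]")
    for label, lo, hi in REGIONS:
        if lo <= ppm < hi:
            return label
    return "aromatic_6_9"  # ppm == 9.0


def region_of_entry(entry: MetaboliteSignature) -> str:
    """Region of an entry's quantification signal."""
    return classify_region(entry.quant_shift_ppm)
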