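"""Detection of drug methylation products in LC-MS peak lists.

Given a parent ion's molecular formula, this module computes the monoisotopic
m/z of the parent and of its +CH2 (methylated), +H2O (hydrate) and +CH2+H2O
(methylated hydrate) derivatives, extracts ion chromatograms inside ppm-scale
m/z windows, and decides which reaction components (enzyme, substrate, methyl
donor) a detected species requires by comparing its presence in the complete
enzymatic reaction against single-omission controls.

Monoisotopic m/z sums standard atomic monoisotopic masses and divides by the
absolute charge.  By default no electron-mass correction is applied — the
convention under which a protonated C10H12O4 cantharidin ion is reported as
197.0814; pass ``electron_correction=True`` to subtract ``charge``
electron masses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: monoisotopic atomic masses (u), most abundant isotope
MONOISOTOPIC_MASS = {
    "C": 12.000000,
    "H": 1.0078250319,
    "O": 15.9949146221,
    "N": 14.0030740052,
    "S": 31.97207069,
    "P": 30.97376151,
}

ELECTRON_MASS = 0.00054857990946

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element->count map with a signed charge."""

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.counts or all(c == 0 for _, c in self.counts):
            raise ValueError("formula must contain at least one atom")
        for elem, count in self.counts:
            if count < 0:
                raise ValueError(f"negative count for {elem}")

    @property
    def count_map(self) -> dict[str, int]:
        return dict(self.counts)

    def add(self, other: "Formula") -> "Formula":
        merged = self.count_map
        for elem, count in other.counts:
            merged[elem] = merged.get(elem, 0) + count
        return Formula(tuple(sorted(merged.items())), charge=self.charge)

    def __str__(self) -> str:
        body = "".join(
            f"{e}{c if c != 1 else ''}" for e, c in self.counts if c > 0
        )
        sign = "+" if self.charge > 0 else "-"
        return body + sign * abs(self.charge)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula with optional trailing +/- charge marks."""
    text = text.strip()
    m = re.match(r"^([A-Za-z0-9]+)(\++|-+)?$", text)
    if not m:
        raise ValueError(f"cannot parse formula {text!r}")
    body, charge_marks = m.group(1), m.group(2) or ""
    charge = len(charge_marks) * (1 if charge_marks.startswith("+") else -1)

    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN_RE.finditer(body):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {body[pos:]!r}")
        elem, digits = match.group(1), match.group(2)
        if not elem:
            break
        if elem not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {elem!r} in {text!r}")
        counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
        pos = match.end()
        if pos == len(body):
            break
    if pos != len(body):
        raise ValueError(f"cannot parse formula {text!r}")
    return Formula(tuple(sorted(counts.items())), charge=charge)


def monoisotopic_mass(formula: Formula) -> float:
    """Neutral monoisotopic mass: sum of atomic monoisotopic masses."""
    return sum(MONOISOTOPIC_MASS[e] * c for e, c in formula.counts)


def monoisotopic_mz(formula: Formula, *, electron_correction: bool = False) -> float:
    """m/z = monoisotopic mass / |charge|; charge 0 is refused."""
    if formula.charge == 0:
        raise ValueError("m/z is undefined for a neutral formula (charge 0)")
    mass = monoisotopic_mass(formula)
    if electron_correction:
        mass -= formula.charge * ELECTRON_MASS
    return mass / abs(formula.charge)


@dataclass(frozen=True)
class IonSpecies:
    name: str
    formula: Formula
    role: str  # parent | methylated | hydrate | methylated-hydrate

    @property
    def mz(self) -> float:
        return monoisotopic_mz(self.formula)


_CH2 = Formula((("C", 1), ("H", 2)))
_H2O = Formula((("H", 2), ("O", 1)))


def methylation_series(parent: Formula, name: str = "parent") -> list[IonSpecies]:
    """Parent, +CH2, +H2O and +CH2+H2O ion species with theoretical m/z."""
    if parent.count_map.get("H", 0) < 1:
        raise ValueError("parent must contain at least one hydrogen")
    return [
        IonSpecies(name, parent, "parent"),
        IonSpecies(f"methyl {name}", parent.add(_CH2), "methylated"),
        IonSpecies(f"hydrated {name}", parent.add(_H2O), "hydrate"),
        IonSpecies(
            f"hydrated methyl {name}", parent.add(_CH2).add(_H2O), "methylated-hydrate"
        ),
    ]


@dataclass(frozen=True)
class MzWindow:
    """Relative mass window: center * (1 +/- ppm * 1e-6)."""

    center: float
    ppm: float = 100.0

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise ValueError("center m/z must be positive")
        if self.ppm < 0:
            raise ValueError("ppm tolerance must be non-negative")

    @property
    def lower(self) -> float:
        return self.center * (1.0 - self.ppm * 1e-6)

    @property
    def upper(self) -> float:
        return self.center * (1.0 + self.ppm * 1e-6)

    def contains(self, mz: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(mz) >= self.lower) & (np.asarray(mz) <= self.upper)


def ppm_window(mz: float, ppm: float = 100.0) -> MzWindow:
    return MzWindow(center=mz, ppm=ppm)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    return (observed - theoretical) / theoretical * 1e6


def extract_eic(peaks: pd.DataFrame, window: MzWindow) -> pd.Series:
    """Extracted ion chromatogram: summed intensity inside the window per scan.

    ``peaks`` needs columns ``rt_min``, ``mz``, ``intensity``.  The returned
    Series is indexed by scan time over the full scan grid of the input, with
    zeros where nothing falls inside the window.
    """
    grid = np.sort(peaks["rt_min"].unique())
    inside = peaks[window.contains(peaks["mz"].to_numpy())]
    trace = inside.groupby("rt_min")["intensity"].sum()
    return trace.reindex(grid, fill_value=0.0).rename("intensity")


@dataclass
class DetectionCall:
    species: str
    presence: dict[str, bool]
    required: frozenset[str]
    apex_rt: float


def detect_species(
    peaks_by_reaction: dict[str, pd.DataFrame],
    reaction_components: dict[str, frozenset[str] | set[str]],
    window: MzWindow,
    *,
    intensity_threshold: float,
    rt_half_window: float = 0.5,
    species_name: str = "species",
) -> DetectionCall:
    """Presence/absence of one ion species across reactions and its dependencies.

    The complete reaction (the one containing every component seen anywhere)
    anchors the retention-time window: presence in each reaction means the EIC
    maximum within ``apex +/- rt_half_window`` minutes reaches the threshold.
    Component ``c`` is deemed required iff the species is present in the
    complete reaction and absent in the reaction omitting exactly ``c``.
    """
    components = {r: frozenset(c) for r, c in reaction_components.items()}
    all_components = frozenset().union(*components.values())
    complete = [r for r, c in components.items() if c == all_components]
    if not complete:
        raise ValueError("no complete reaction (containing all components) in input")
    complete_id = complete[0]

    empty = pd.DataFrame(columns=["rt_min", "mz", "intensity"])
    traces = {
        # a reaction with no recorded peaks at all is an empty chromatogram
        r: extract_eic(peaks_by_reaction.get(r, empty), window)
        for r in components
    }
    full_trace = traces[complete_id]
    apex_rt = float(full_trace.idxmax()) if len(full_trace) else float("nan")

    presence = {}
    for rid, trace in traces.items():
        in_window = trace[
            (trace.index >= apex_rt - rt_half_window)
            & (trace.index <= apex_rt + rt_half_window)
        ]
        presence[rid] = bool(len(in_window)) and float(in_window.max()) >= intensity_threshold

    required = set()
    if presence[complete_id]:
        for comp in all_components:
            omitting = [r for r, c in components.items() if c == all_components - {comp}]
            if omitting and not presence[omitting[0]]:
                required.add(comp)
    return DetectionCall(
        species=species_name,
        presence=presence,
        required=frozenset(required),
        apex_rt=apex_rt,
    )


def read_mzml_peaks(path) -> pd.DataFrame:
    """Thin optional mzML reader returning the peak-list record stream.

    Flattens MS1 centroid arrays into the same (rt_min, mz, intensity) frame
    the CSV reader produces.  Requires pyteomics.
    """
    from pyteomics import mzml  # optional dependency, imported lazily

    rows = []
    with mzml.read(str(path)) as reader:
        for scan in reader:
            if scan.get("ms level", 1) != 1:
                continue
            rt = scan["scanList"]["scan"][0]["scan start time"]
            for mz, inten in zip(scan["m/z array"], scan["intensity array"]):
                rows.append((float(rt), float(mz), float(inten)))
    return pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])


def detection_report(
    peaks_by_reaction: dict[str, pd.DataFrame],
    reaction_components: dict[str, frozenset[str] | set[str]],
    parent: Formula,
    *,
    ppm: float = 100.0,
    intensity_threshold: float,
    rt_half_window: float = 0.5,
    parent_name: str = "parent",
) -> pd.DataFrame:
    """Run the four-species methylation series through detect_species."""
    rows = []
    for sp in methylation_series(parent, name=parent_name):
        call = detect_species(
            peaks_by_reaction,
            reaction_components,
            ppm_window(sp.mz, ppm),
            intensity_threshold=intensity_threshold,
            rt_half_window=rt_half_window,
            species_name=sp.name,
        )
        rows.append(
            {
                "species": sp.name,
                "role": sp.role,
                "mz": round(sp.mz, 4),
                "apex_rt": call.apex_rt,
                "required": "+".join(sorted(call.required)) or "-",
                **{f"present_{r}": v for r, v in sorted(call.presence.items())},
            }
        )
    return pd.DataFrame(rows)
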