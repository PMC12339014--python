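"""Chemical formulas, isotope tables, and isotopologue fine structure.

Defines the monitored species of a target ion (e.g. the M0, 13C1, 13C2 and
18O1 isotopologues of protonated or sodiated methyl stearate) by expanding
the molecular formula over an isotope abundance table.  Abundances are exact
multinomial-expansion terms normalised over *all* isotopologues; pruning only
shortens the returned list, it never renormalises.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "ELECTRON_MASS",
    "ADDUCTS",
    "Isotope",
    "IsotopeTable",
    "IsotopologueSpecies",
    "TargetIon",
    "default_isotope_table",
    "load_isotope_table",
    "parse_formula",
    "fine_structure",
    "species_mz",
]

ELECTRON_MASS = 0.000548579909065  # Da

#: Adduct kind -> (element symbol added, charge carrier sign). Both supported
#: adducts are single-atom cation adducts in positive mode.
ADDUCTS = {"proton": "H", "sodium": "Na"}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Isotope:
    mass_number: int
    mass: float       # Da
    abundance: float  # mole fraction


class IsotopeTable:
    """Per-element isotope masses and abundances.

    Invariants enforced at construction: abundances per element sum to one
    within 1e-9 and masses increase strictly with mass number.
    """

    def __init__(self, data: dict[str, list[Isotope]]):
        for element, isotopes in data.items():
            total = sum(iso.abundance for iso in isotopes)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"abundances for {element} sum to {total!r}, expected 1"
                )
            ordered = sorted(isotopes, key=lambda iso: iso.mass_number)
            masses = [iso.mass for iso in ordered]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"isotope masses for {element} not increasing")
            data[element] = ordered
        self._data = data

    def __contains__(self, element: str) -> bool:
        return element in self._data

    def __getitem__(self, element: str) -> list[Isotope]:
        return self._data[element]

    def elements(self) -> list[str]:
        return list(self._data)

    def principal(self, element: str) -> Isotope:
        """Most abundant isotope of *element*."""
        return max(self._data[element], key=lambda iso: iso.abundance)

    def with_ratio(self, element: str, minor_mass_number: int, ratio: float) -> "IsotopeTable":
        """Return a copy with the *minor/principal* abundance ratio of one
        element replaced (two-isotope elements only).

        Used by the session simulator to realise a configured delta value by
        shifting the 13C/12C ratio while leaving every other element at its
        reference composition.
        """
        isotopes = self._data[element]
        if len(isotopes) != 2:
            raise ValueError(f"{element} is not a two-isotope element")
        major = self.principal(element)
        minor = next(i for i in isotopes if i.mass_number == minor_mass_number)
        if minor is major:
            raise ValueError("minor isotope equals principal isotope")
        x_minor = ratio / (1.0 + ratio)
        new = dict(self._data)
        new[element] = [
            Isotope(major.mass_number, major.mass, 1.0 - x_minor),
            Isotope(minor.mass_number, minor.mass, x_minor),
        ]
        return IsotopeTable(new)


def load_isotope_table(path) -> IsotopeTable:
    """Load an isotope table from a tab-delimited file with header
    ``element  mass_number  mass_da  abundance``."""
    data: dict[str, list[Isotope]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if header[:4] != ["element", "mass_number", "mass_da", "abundance"]:
            raise ValueError(f"unrecognised isotope table header: {header}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            element, a, m, p = line.split()
            data.setdefault(element, []).append(Isotope(int(a), float(m), float(p)))
    return IsotopeTable(data)


_DEFAULT_TABLE: IsotopeTable | None = None


def default_isotope_table() -> IsotopeTable:
    """Bundled IUPAC standard atomic masses and isotopic abundances."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        ref = resources.files("orbidelta.data") / "isotopes.tsv"
        with resources.as_file(ref) as path:
            _DEFAULT_TABLE = load_isotope_table(path)
    return _DEFAULT_TABLE


def parse_formula(text: str, table: IsotopeTable | None = None) -> dict[str, int]:
    """Parse a Hill-style molecular formula such as ``"C19H38O2"``.

    Counts default to 1 (``"C"`` -> ``{"C": 1}``); explicit zero counts are
    rejected, as are element symbols absent from the isotope table.
    """
    table = table or default_isotope_table()
    if not text or not text.strip():
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        if not match.group(0):
            break
        pos = match.end()
        element = match.group(1)
        if element not in table:
            raise ValueError(f"unknown element {element!r} in {text!r}")
        n = int(match.group(2)) if match.group(2) else 1
        if n <= 0:
            raise ValueError(f"non-positive count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + n
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    if not counts:
        raise ValueError(f"no atoms in formula {text!r}")
    return counts


@dataclass(frozen=True)
class IsotopologueSpecies:
    """One isotopic substitution pattern of a molecular ion.

    ``substitutions`` lists minor-isotope replacements as
    ``(element, mass_number, count)``; the monoisotopic species has an empty
    tuple and label ``"M0"``.  ``abundance`` is the species' fraction of the
    full isotopologue population; ``mz`` is exact for the declared adduct and
    charge.
    """

    substitutions: tuple[tuple[str, int, int], ...]
    abundance: float
    mz: float
    label: str

    def __post_init__(self):
        if not 0.0 < self.abundance <= 1.0:
            raise ValueError(f"abundance {self.abundance} outside (0, 1]")
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


@dataclass
class TargetIon:
    """A monitored molecular ion: formula, adduct, charge and the
    isotopologue species tracked inside its SIM window."""

    formula: dict[str, int]
    adduct: str = "proton"
    charge: int = 1
    species: list[IsotopologueSpecies] = field(default_factory=list)
    ppm_tolerance: float = 5.0

    def __post_init__(self):
        if self.adduct not in ADDUCTS:
            raise ValueError(f"unknown adduct {self.adduct!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        labels = [s.label for s in self.species]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate species labels")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.species]

    def species_by_label(self, label: str) -> IsotopologueSpecies:
        for s in self.species:
            if s.label == label:
                return s
        raise KeyError(label)


def _ion_composition(formula: dict[str, int], adduct: str, table: IsotopeTable) -> dict[str, int]:
    if not formula:
        raise ValueError("empty formula")
    comp = dict(formula)
    add_el = ADDUCTS[adduct]
    if add_el not in table:
        raise ValueError(f"adduct element {add_el} missing from isotope table")
    comp[add_el] = comp.get(add_el, 0) + 1
    return comp


def _element_patterns(element: str, n: int, table: IsotopeTable, floor: float):
    """All isotope composition vectors of *n* atoms of *element* with their
    multinomial probabilities, mass sums and minor-substitution lists.

    Terms with probability below *floor* are dropped; at floor 1e-15 the
    truncation error of the full expansion stays far below 1e-9.
    """
    isotopes = table[element]
    principal = table.principal(element)
    out = []
    k = len(isotopes)
    for split in itertools.combinations_with_replacement(range(k), n):
        counts = [0] * k
        for idx in split:
            counts[idx] += 1
        logp = math.lgamma(n + 1)
        ok = True
        for c, iso in zip(counts, isotopes):
            if c and iso.abundance == 0.0:
                ok = False
                break
            logp -= math.lgamma(c + 1)
            if c:
                logp += c * math.log(iso.abundance)
        if not ok:
            continue
        prob = math.exp(logp)
        if prob < floor:
            continue
        mass = sum(c * iso.mass for c, iso in zip(counts, isotopes))
        subs = tuple(
            (element, iso.mass_number, c)
            for c, iso in zip(counts, isotopes)
            if c and iso is not principal
        )
        out.append((prob, mass, subs))
    return out


def _label(substitutions: tuple[tuple[str, int, int], ...]) -> str:
    if not substitutions:
        return "M0"
    parts = sorted(substitutions, key=lambda s: (s[0], s[1]))
    return "+".join(f"{a}{el}{c}" for el, a, c in parts)


def fine_structure(
    formula: dict[str, int],
    adduct: str = "proton",
    charge: int = 1,
    prune: float = 1e-6,
    table: IsotopeTable | None = None,
) -> list[IsotopologueSpecies]:
    """Isotopologue fine structure of ``[M + adduct]^charge+``.

    The adduct atom participates in the isotopic expansion (a proton adduct
    adds one H site; sodium is monoisotopic).  Species are returned sorted by
    descending abundance; entries below *prune* are omitted but abundances
    remain normalised over the complete expansion.
    """
    if not 0.0 <= prune < 1.0:
        raise ValueError("prune must be in [0, 1)")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    table = table or default_isotope_table()
    comp = _ion_composition(formula, adduct, table)

    combined = [(1.0, 0.0, ())]
    for element, n in comp.items():
        patterns = _element_patterns(element, n, table, floor=1e-15)
        combined = [
            (p1 * p2, m1 + m2, s1 + s2)
            for p1, m1, s1 in combined
            for p2, m2, s2 in patterns
        ]
    species = []
    for prob, mass, subs in combined:
        if prob < prune:
            continue
        mz = (mass - charge * ELECTRON_MASS) / charge
        subs = tuple(sorted(subs))
        species.append(
            IsotopologueSpecies(
                substitutions=subs, abundance=prob, mz=mz, label=_label(subs)
            )
        )
    species.sort(key=lambda s: -s.abundance)
    return species


def species_mz(
    species: IsotopologueSpecies,
    formula: dict[str, int],
    adduct: str = "proton",
    charge: int = 1,
    table: IsotopeTable | None = None,
) -> float:
    """Exact m/z of a substitution pattern of ``[M + adduct]^charge+``.

    m/z = (sum of atomic masses with substitutions + adduct mass
    - charge x electron mass) / charge.
    """
    table = table or default_isotope_table()
    comp = _ion_composition(formula, adduct, table)
    subs = {(el, a): c for el, a, c in species.substitutions}
    for (el, a), c in subs.items():
        if c > comp.get(el, 0):
            raise ValueError(f"substitution count for {a}{el} exceeds atom count")
    mass = 0.0
    for element, n in comp.items():
        principal = table.principal(element)
        n_sub = 0
        for iso in table[element]:
            c = subs.get((element, iso.mass_number), 0)
            if iso is principal:
                continue
            mass += c * iso.mass
            n_sub += c
        mass += (n - n_sub) * principal.mass
    return (mass - charge * ELECTRON_MASS) / charge


def make_target(
    formula: str | dict[str, int],
    adduct: str = "proton",
    charge: int = 1,
    labels: Iterable[str] = ("M0", "13C1", "13C2", "18O1"),
    ppm_tolerance: float = 5.0,
    table: IsotopeTable | None = None,
) -> TargetIon:
    """Convenience constructor: a TargetIon monitoring the named species."""
    if isinstance(formula, str):
        formula = parse_formula(formula, table)
    structure = {s.label: s for s in fine_structure(formula, adduct, charge, 1e-9, table)}
    missing = [lb for lb in labels if lb not in structure]
    if missing:
        raise ValueError(f"species not found in fine structure: {missing}")
    return TargetIon(
        formula=formula,
        adduct=adduct,
        charge=charge,
        species=[structure[lb] for lb in labels],
        ppm_tolerance=ppm_tolerance,
    )
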