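"""Elemental compositions, monoisotopic masses and isotopologue envelopes.

Peptide species carry an optional N-terminal acetyl group in two isotopic
versions: the light acetyl (CH3-CO-) and a heavy acetyl (CD3-[13C]O-) in
which one carbon is carbon-13 and the three methyl hydrogens are deuterium.
The heavy version shifts the peptide mass by a nominal +4 amu (exactly
4.022185 Da), placing its monoisotopic peak beyond the natural-abundance
isotopologue envelope (k = 0..3) of the light peptide, so a light/heavy
pair can be quantified in a single MALDI-TOF spectrum without peak overlap.

Labelled positions are modelled as explicit-isotope pseudo-elements
(``13C``, ``2H``) with unit abundance; unlabelled elements follow natural
abundances from an embedded IUPAC table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np

__all__ = [
    "ElementalComposition",
    "IsotopePattern",
    "PeptideSpecies",
    "AdductSpecies",
    "ISOTOPE_TABLE",
    "RESIDUE_FORMULAS",
    "ADDUCT_SHIFTS",
    "ELECTRON_MASS",
    "parse_formula",
    "compose_peptide",
    "monoisotopic_mass",
    "isotope_pattern",
    "adduct_mz",
    "label_mass_shift",
    "overlap_risk",
    "FormulaError",
    "ResidueError",
]


class FormulaError(ValueError):
    """Raised for malformed or unknown-element formula strings."""


class ResidueError(KeyError):
    """Raised when a sequence contains a residue code with no formula."""


# Isotope masses (Da) and natural abundance fractions, IUPAC/AME standard
# values.  Pseudo-elements "13C" and "2H" model chemically defined labelled
# positions and therefore carry a single isotope at abundance 1.
ISOTOPE_TABLE: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177812, 0.000115)),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.00307400443, 0.99636), (15.00010889888, 0.00364)),
    "O": (
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ),
    "S": (
        (31.9720711744, 0.9499),
        (32.9714589098, 0.0075),
        (33.967867004, 0.0425),
        (35.96708071, 0.0001),
    ),
    "Na": ((22.9897692820, 1.0),),
    "K": (
        (38.9637064864, 0.932581),
        (39.963998166, 0.000117),
        (40.9618252579, 0.067302),
    ),
    "13C": ((13.00335483507, 1.0),),
    "2H": ((2.01410177812, 1.0),),
}

ELECTRON_MASS = 0.000548579909065

# Singly-charged cation adduct shifts: cation mass minus one electron.
ADDUCT_SHIFTS: Dict[str, float] = {
    "H": ISOTOPE_TABLE["H"][0][0] - ELECTRON_MASS,
    "Na": ISOTOPE_TABLE["Na"][0][0] - ELECTRON_MASS,
    "K": ISOTOPE_TABLE["K"][0][0] - ELECTRON_MASS,
}


@dataclass(frozen=True)
class ElementalComposition:
    """A multiset of element -> count; the basis for masses and envelopes.

    Counts are non-negative integers.  Addition and subtraction are
    element-wise; subtracting below zero raises ``ValueError``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in ISOTOPE_TABLE:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            left = merged.get(el, 0) - n
            if left < 0:
                raise ValueError(f"subtraction yields negative count for {el}")
            merged[el] = left
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        if k < 0:
            raise ValueError("multiplier must be non-negative")
        return ElementalComposition({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def hill_formula(self) -> str:
        """Canonical Hill-notation string; explicit isotopes in brackets."""

        def fmt(el: str) -> str:
            n = self.counts[el]
            sym = f"[{el}]" if el[0].isdigit() else el
            return sym if n == 1 else f"{sym}{n}"

        order: List[str] = []
        for el in ("C", "13C", "H", "2H"):
            if el in self.counts:
                order.append(el)
        rest = sorted(el for el in self.counts if el not in ("C", "13C", "H", "2H"))
        return "".join(fmt(el) for el in order + rest)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_formula()


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?|\[\d+[A-Z][a-z]?\])(\d*)")


def parse_formula(text: str) -> ElementalComposition:
    """Parse a Hill-notation formula like ``"C6H11NO"`` or ``"C[13C]H2[2H]3O"``.

    Explicit isotopes are written in brackets (``[13C]``, ``[2H]``).
    Unknown element symbols and malformed strings raise :class:`FormulaError`
    naming the offending token.
    """
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula near {text[pos:m.start()]!r} in {text!r}")
        el = m.group(1).strip("[]")
        if el not in ISOTOPE_TABLE:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        n = int(m.group(2)) if m.group(2) else 1
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula near {text[pos:]!r} in {text!r}")
    return ElementalComposition(counts)


# Residue (internal) compositions of the 20 canonical amino acids.
# D-amino acids share the composition of their L-forms; non-natural residues
# are supplied by the user through a residue-formula table.
RESIDUE_FORMULAS: Dict[str, ElementalComposition] = {
    code: parse_formula(f)
    for code, f in {
        "G": "C2H3NO",
        "A": "C3H5NO",
        "S": "C3H5NO2",
        "P": "C5H7NO",
        "V": "C5H9NO",
        "T": "C4H7NO2",
        "C": "C3H5NOS",
        "L": "C6H11NO",
        "I": "C6H11NO",
        "N": "C4H6N2O2",
        "D": "C4H5NO3",
        "Q": "C5H8N2O2",
        "K": "C6H12N2O",
        "E": "C5H7NO3",
        "M": "C5H9NOS",
        "H": "C6H7N3O",
        "F": "C9H9NO",
        "R": "C6H12N4O",
        "Y": "C9H9NO2",
        "W": "C11H10N2O",
    }.items()
}

# Net composition changes for terminal states.
_N_TERM_H = parse_formula("H")
_C_TERM = {
    "free_acid": parse_formula("OH"),
    "amide": parse_formula("NH2"),
}
# Acetylation replaces one amine H by CH3CO- (net +C2H2O); the heavy acetyl
# is CD3-[13C]O- (net +C[13C][2H]3O-H relative to the free amine).
_ACETYL_LIGHT = parse_formula("C2H2O")
_ACETYL_HEAVY_ADD = parse_formula("C[13C][2H]3O")

N_TERMINI = ("free", "acetyl_light", "acetyl_heavy")
C_TERMINI = ("free_acid", "amide")


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide defined by sequence, terminal groups and label state.

    ``sequence`` is a string of one-letter residue codes looked up in
    ``residue_formulas`` (defaults to the built-in canonical 20).  The label
    state (light/heavy) is carried by the N-terminal acetyl choice.
    """

    sequence: str
    n_terminus: str = "free"
    c_terminus: str = "free_acid"
    residue_formulas: Mapping[str, ElementalComposition] = field(
        default_factory=lambda: RESIDUE_FORMULAS, repr=False
    )
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_terminus not in N_TERMINI:
            raise ValueError(f"n_terminus must be one of {N_TERMINI}, got {self.n_terminus!r}")
        if self.c_terminus not in C_TERMINI:
            raise ValueError(f"c_terminus must be one of {C_TERMINI}, got {self.c_terminus!r}")
        missing = sorted({c for c in self.sequence if c not in self.residue_formulas})
        if missing:
            raise ResidueError(f"no formula for residue code(s): {', '.join(missing)}")

    @property
    def label_state(self) -> str:
        return "heavy" if self.n_terminus == "acetyl_heavy" else "light"

    def with_n_terminus(self, n_terminus: str) -> "PeptideSpecies":
        return PeptideSpecies(
            self.sequence, n_terminus, self.c_terminus, self.residue_formulas, self.name
        )

    def composition(self) -> ElementalComposition:
        return compose_peptide(self)

    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.composition())


def compose_peptide(species: PeptideSpecies) -> ElementalComposition:
    """Elemental composition: residue sum + terminal groups + label."""
    total = ElementalComposition()
    for code in species.sequence:
        total = total + species.residue_formulas[code]
    total = total + _N_TERM_H + _C_TERM[species.c_terminus]
    if species.n_terminus == "acetyl_light":
        total = total + _ACETYL_LIGHT
    elif species.n_terminus == "acetyl_heavy":
        total = (total + _ACETYL_HEAVY_ADD) - _N_TERM_H
    return total


def monoisotopic_mass(c: ElementalComposition) -> float:
    """Mass using each element's most abundant isotope (explicit isotopes
    use their own mass)."""
    return sum(n * ISOTOPE_TABLE[el][0][0] for el, n in c.counts.items())


def label_mass_shift() -> float:
    """Exact heavy-minus-light acetyl mass shift, nominally +4 amu.

    (m(13C) - m(12C)) + 3 (m(2H) - m(1H)) = 4.022185 Da.
    """
    d_c = ISOTOPE_TABLE["13C"][0][0] - ISOTOPE_TABLE["C"][0][0]
    d_h = ISOTOPE_TABLE["2H"][0][0] - ISOTOPE_TABLE["H"][0][0]
    return d_c + 3.0 * d_h


@dataclass(frozen=True)
class AdductSpecies:
    """A singly charged cation adduct: [M+H]+, [M+Na]+ or [M+K]+."""

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ADDUCT_SHIFTS:
            raise ValueError(f"unknown adduct kind {self.kind!r}; expected one of "
                             f"{sorted(ADDUCT_SHIFTS)}")

    @property
    def charge(self) -> int:
        return 1

    @property
    def mass_shift(self) -> float:
        return ADDUCT_SHIFTS[self.kind]


def adduct_mz(neutral_mass: float, adduct: AdductSpecies | str) -> float:
    """m/z of the singly charged adduct, with electron-mass correction."""
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if isinstance(adduct, str):
        adduct = AdductSpecies(adduct)
    return neutral_mass + adduct.mass_shift


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue envelope aggregated by nominal mass offset k.

    ``offsets`` are non-negative integers relative to the monoisotopic peak,
    ``masses`` the abundance-weighted exact neutral mass per offset, and
    ``abundances`` the relative fractions (normalized to sum to 1).
    """

    offsets: Tuple[int, ...]
    masses: Tuple[float, ...]
    abundances: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.offsets) == len(self.masses) == len(self.abundances)):
            raise ValueError("offsets, masses and abundances must align")
        if any(a < 0 for a in self.abundances):
            raise ValueError("abundances must be non-negative")
        if any(m2 <= m1 for m1, m2 in zip(self.masses, self.masses[1:])):
            raise ValueError("masses must be strictly increasing")

    def abundance(self, k: int) -> float:
        try:
            return self.abundances[self.offsets.index(k)]
        except ValueError:
            return 0.0

    def mass(self, k: int) -> float:
        return self.masses[self.offsets.index(k)]

    def items(self) -> Iterable[Tuple[int, float, float]]:
        return zip(self.offsets, self.masses, self.abundances)


def _single_atom_distribution(el: str) -> Tuple[np.ndarray, np.ndarray]:
    """(probability, first-moment-of-mass) arrays indexed by nominal offset."""
    isotopes = ISOTOPE_TABLE[el]
    base = isotopes[0][0]
    kmax = max(int(round(m - base)) for m, _ in isotopes)
    p = np.zeros(kmax + 1)
    mom = np.zeros(kmax + 1)
    for m, a in isotopes:
        k = int(round(m - base))
        p[k] += a
        mom[k] += a * m
    return p, mom


def _convolve(a: Tuple[np.ndarray, np.ndarray],
              b: Tuple[np.ndarray, np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    pa, ma = a
    pb, mb = b
    p = np.convolve(pa, pb)
    mom = np.convolve(ma, pb) + np.convolve(pa, mb)
    return p, mom


def isotope_pattern(c: ElementalComposition, truncation: float = 1e-10) -> IsotopePattern:
    """Isotopologue envelope of a composition, binned by nominal mass.

    Per-element multinomial distributions (computed by repeated squaring of
    the single-atom distribution) are combined by convolution over nominal
    mass offsets; each bin's exact mass is the abundance-weighted mean over
    the isotopologues it aggregates.  Offsets with abundance below
    ``truncation`` past the last retained peak are pruned, and the envelope
    is renormalized to sum to exactly 1.
    """
    if not 0 < truncation < 1:
        raise ValueError("truncation must be in (0, 1)")
    # identity under convolution: probability 1, mass moment 0 at offset 0
    acc: Tuple[np.ndarray, np.ndarray] = (np.array([1.0]), np.array([0.0]))
    for el, n in sorted(c.counts.items()):
        single = _single_atom_distribution(el)
        power, k = single, n
        # exponentiation by squaring
        first = True
        while k:
            if k & 1:
                acc_el = power if first else _convolve(acc_el, power)
                first = False
            k >>= 1
            if k:
                power = _convolve(power, power)
        if not first:
            acc = _convolve(acc, acc_el)
    p, mom = acc
    keep = int(np.max(np.nonzero(p >= truncation)[0])) if np.any(p >= truncation) else 0
    p, mom = p[: keep + 1], mom[: keep + 1]
    offsets = [k for k in range(len(p)) if p[k] > 0]
    total = float(np.sum(p))
    masses = tuple(float(mom[k] / p[k]) for k in offsets)
    abundances = tuple(float(p[k] / total) for k in offsets)
    return IsotopePattern(tuple(offsets), masses, abundances)


@dataclass(frozen=True)
class OverlapReport:
    """Summed light-envelope abundance in the heavy-peak region (k >= 4)."""

    overlap_abundance: float
    min_fraction: float
    flagged: bool


def overlap_risk(light: IsotopePattern, min_fraction: float = 0.05) -> OverlapReport:
    """Check whether the light envelope bleeds into the heavy region.

    The heavy monoisotopic peak lands at nominal offset +4 from the light
    monoisotopic peak; quantification of the heavy standard is safe when the
    light envelope's total abundance at k >= 4 is negligible.
    """
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    overlap = float(sum(a for k, _, a in light.items() if k >= 4))
    return OverlapReport(overlap, min_fraction, overlap > min_fraction)
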