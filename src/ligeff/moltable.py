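"""Composition descriptors from molecular formulas.

The size descriptors driving efficiency metrics — molecular weight (MW, Da),
heavy atom count (HAC) and all-atom count (AC) — depend only on elemental
composition, not on connectivity or stereochemistry.  The canonical input is
therefore a plain Hill-notation molecular formula; SMILES parsing (through
rdkit, with implicit hydrogens made explicit) is an optional convenience.

Element counts are plain ``dict[str, int]`` maps with the convention that
absent elements are absent, never stored as zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from .masses import ATOMIC_MASSES, atomic_mass

ElementCounts = dict[str, int]

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for formulas that cannot be read as plain Hill notation."""


def parse_formula(formula: str) -> ElementCounts:
    """Parse a Hill-notation molecular formula into element counts.

    Only a flat sequence of ``<element symbol><optional count>`` tokens is
    accepted.  Isotope labels, charges, hydrate dots, parentheses and salts
    are rejected rather than guessed: a silently misparsed formula would
    corrupt every MW-driven trend downstream.

    Parameters
    ----------
    formula : str
        e.g. ``"C6H5Br"``.  An omitted count means 1.

    Returns
    -------
    dict
        Element symbol -> count, counts >= 1.

    Examples
    --------
    >>> parse_formula("C6H6")
    {'C': 6, 'H': 6}
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty molecular formula")
    formula = formula.strip()
    counts: ElementCounts = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN_RE.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed token at position {pos} in formula {formula!r}: "
                f"{formula[pos:pos + 4]!r}"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ATOMIC_MASSES:
            raise FormulaError(f"unknown element symbol {symbol!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"zero count for {symbol!r} in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Serialize element counts to Hill notation (C, H, then alphabetical)."""
    _validate_counts(counts)
    symbols = sorted(counts)
    ordered = [s for s in ("C", "H") if s in counts]
    ordered += [s for s in symbols if s not in ("C", "H")]
    return "".join(f"{s}{counts[s]}" if counts[s] > 1 else s for s in ordered)


def _validate_counts(counts: Mapping[str, int]) -> None:
    if not counts:
        raise FormulaError("empty element count map")
    for symbol, n in counts.items():
        if symbol not in ATOMIC_MASSES:
            raise KeyError(f"unknown element symbol {symbol!r}")
        if not isinstance(n, (int,)) or n < 1:
            raise FormulaError(f"invalid count {n!r} for element {symbol!r}")


def compute_mw(counts: Mapping[str, int]) -> float:
    """Molecular weight in Daltons: sum of atomic mass contributions."""
    _validate_counts(counts)
    return sum(n * atomic_mass(symbol) for symbol, n in counts.items())


def compute_hac(counts: Mapping[str, int]) -> int:
    """Heavy (non-hydrogen) atom count."""
    _validate_counts(counts)
    return sum(n for symbol, n in counts.items() if symbol != "H")


def compute_ac(counts: Mapping[str, int]) -> int:
    """All-atom count, hydrogens included."""
    _validate_counts(counts)
    return sum(counts.values())


def ratio_descriptor(numerator: float, denominator: float) -> float:
    """Ratio-type descriptor such as Br/AC or MW/HAC.

    The denominator must be strictly positive; ratio descriptors are only
    defined for a positive size measure.
    """
    if denominator <= 0:
        raise ValueError(f"ratio denominator must be > 0, got {denominator}")
    return numerator / denominator


def mass_fraction(counts: Mapping[str, int], element: str) -> float:
    """Weight fraction of *element* in the molecule, in [0, 1].

    Percentage content is the textbook example of a weight-normalized
    (per-gram) descriptor: the fraction of the sample mass contributed by
    one element.  Returns 0 for an element absent from the molecule.
    """
    _validate_counts(counts)
    mass = atomic_mass(element)  # raises for unknown symbols
    if element not in counts:
        return 0.0
    return counts[element] * mass / compute_mw(counts)


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, composition and size descriptors.

    ``mw_da`` is always recomputed from ``counts`` so the MW column can
    never drift from the composition it claims to describe.
    """

    id: str
    counts: ElementCounts
    mw_da: float = field(init=False)
    hac: int = field(init=False)
    ac: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mw_da", compute_mw(self.counts))
        object.__setattr__(self, "hac", compute_hac(self.counts))
        object.__setattr__(self, "ac", compute_ac(self.counts))
        if self.hac < 1:
            raise FormulaError(
                f"molecule {self.id!r} has no heavy atoms ({self.counts!r})"
            )

    @classmethod
    def from_formula(cls, id: str, formula: str) -> "MoleculeRecord":
        return cls(id=id, counts=parse_formula(formula))

    @property
    def formula(self) -> str:
        return format_formula(self.counts)

    def element_count(self, element: str) -> int:
        return self.counts.get(element, 0)


def counts_from_smiles(smiles: str) -> ElementCounts:
    """Element counts from a SMILES string via rdkit (optional dependency).

    Implicit hydrogens are made explicit before counting, so AC includes
    them.  Connectivity and stereochemistry are discarded: only composition
    feeds the descriptors.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "SMILES input requires rdkit; install the 'chem' extra or "
            "provide a molecular formula instead"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormulaError(f"unparseable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    counts: ElementCounts = {}
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        counts[symbol] = counts.get(symbol, 0) + 1
    return counts
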