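"""Monoisotopic-mass arithmetic and modified-nucleoside peak annotation.

Implements the reasoning used to identify sugar-decorated DNA bases from
LC-MS data: elemental-formula arithmetic over C/H/N/O/P, monoisotopic
masses, singly-charged adduct m/z ([M+H]+ / [M-H]-), enumeration of
(base species + modification delta) candidates explaining an observed
peak, and MS2 fragment assignment via single or chained neutral losses.

The shipped libraries cover the canonical deoxynucleotides, cytosine
derivatives, the pentosyl (C5H8O4, a deoxypentose bound through an extra
O-glycosidic oxygen) and glycosyl deltas, and the neutral losses relevant
to glycosylated pyrimidine nucleosides.  Tolerances are always explicit:
instrument peaks printed to two decimals are matched within 0.03 Da,
four-decimal peaks within 0.005 Da.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

#: Monoisotopic masses (Da) of the supported elements.
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
}

#: Proton mass used for [M+H]+ / [M-H]- adducts.
PROTON = 1.00728

ADDUCTS = ("[M+H]+", "[M-H]-")

_FORMULA_RX = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula:
    """An elemental composition over C/H/N/O/P with non-negative counts."""

    __slots__ = ("counts",)

    def __init__(self, counts: Optional[dict[str, int]] = None):
        self.counts: dict[str, int] = {}
        for el, n in (counts or {}).items():
            if el not in MONOISOTOPIC:
                raise ValueError(f"unsupported element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el!r}")
            if n:
                self.counts[el] = int(n)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``"C5H8O4"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RX.finditer(text.strip()):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            el, n = m.group(1), int(m.group(2) or 1)
            if el not in MONOISOTOPIC:
                raise ValueError(f"unsupported element {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + n
        if pos != len(text.strip()):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) - n
            if counts[el] < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count ({self} - {other})"
                )
        return Formula(counts)

    def contains(self, other: "Formula") -> bool:
        return all(self.counts.get(el, 0) >= n for el, n in other.counts.items())

    def __eq__(self, other) -> bool:
        return isinstance(other, Formula) and self.counts == other.counts

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def __str__(self) -> str:
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
            for el in "CHNOP"
            if el in self.counts
        ) or "(empty)"

    def __repr__(self) -> str:
        return f"Formula({self})"


def monoisotopic_mass(formula: Formula) -> float:
    """Sum of tabulated monoisotopic element masses (Da)."""
    return sum(MONOISOTOPIC[el] * n for el, n in formula.counts.items())


def adduct_mz(formula: Formula, adduct: str) -> float:
    """m/z of the singly charged adduct: M ± one proton."""
    m = monoisotopic_mass(formula)
    if adduct == "[M+H]+":
        return m + PROTON
    if adduct == "[M-H]-":
        return m - PROTON
    raise ValueError(f"unsupported adduct {adduct!r}; expected one of {ADDUCTS}")


# --- shipped libraries -------------------------------------------------

BASE_SPECIES: dict[str, Formula] = {
    "cytosine": Formula.parse("C4H5N3O"),
    "5-hydroxymethylcytosine": Formula.parse("C5H7N3O2"),
    "hydroxycytosine": Formula.parse("C4H5N3O2"),
    "deoxycytidine": Formula.parse("C9H13N3O4"),
    "dCMP": Formula.parse("C9H14N3O7P"),
    "dTMP": Formula.parse("C10H15N2O8P"),
    "dAMP": Formula.parse("C10H14N5O6P"),
    "dGMP": Formula.parse("C10H14N5O7P"),
    "UDP-xylose": Formula.parse("C14H22N2O16P2"),
}

#: Net compositions added by a covalent base modification.  "pentose+O" is
#: the deoxypentose-with-O-glycosidic-oxygen decoration (net C5H8O4); its
#: exact attachment chemistry is not encoded, only the composition.
DELTAS: dict[str, Formula] = {
    "pentose+O": Formula.parse("C5H8O4"),
    "deoxypentosyl": Formula.parse("C5H8O3"),
    "glucosyl": Formula.parse("C6H10O5"),
    "methyl": Formula.parse("CH2"),
    "hydroxymethyl": Formula.parse("CH2O"),
}

#: Neutral losses observed in MS2 of glycosylated nucleosides.
LOSSES: dict[str, Formula] = {
    "water": Formula.parse("H2O"),
    "deoxyribose": Formula.parse("C5H8O3"),
    "pentosyl": Formula.parse("C5H8O3"),
    "phosphate": Formula.parse("HPO3"),
}

#: Default matching tolerances (Da) by printed precision of the peak.
TOL_COARSE = 0.03  # 2-decimal instrument peaks
TOL_FINE = 0.005  # 4-decimal peaks


@dataclass
class ModificationCandidate:
    """One (base species + optional delta) explanation of an observed m/z."""

    base_name: str
    base_formula: Formula
    delta_name: Optional[str]
    delta_formula: Optional[Formula]
    adduct: str
    theoretical_mz: float
    observed_mz: float

    @property
    def abs_error(self) -> float:
        return abs(self.theoretical_mz - self.observed_mz)

    @property
    def formula(self) -> Formula:
        if self.delta_formula is None:
            return self.base_formula
        return self.base_formula + self.delta_formula


@dataclass
class FragmentAssignment:
    """A fragment m/z explained by one or two chained neutral losses."""

    fragment_mz: float
    losses: tuple[str, ...]
    remaining: Optional[Formula]
    theoretical_mz: Optional[float]
    abs_error: Optional[float]
    assigned: bool


def explain_peak(
    observed_mz: float,
    base_species: list[tuple[str, Formula]],
    delta_library: list[tuple[str, Formula]],
    adduct: str,
    tol_da: float,
) -> list[ModificationCandidate]:
    """All (base, delta) pairs within ``tol_da`` of an observed m/z.

    The delta may be absent (the unmodified species).  Results are sorted
    ascending by absolute error, then by name for determinism.  A zero
    tolerance admits only exact matches.
    """
    if tol_da < 0:
        raise ValueError("tol_da must be >= 0")
    out = []
    deltas: list[tuple[Optional[str], Optional[Formula]]] = [(None, None)]
    deltas.extend(delta_library)
    for base_name, base_f in base_species:
        for delta_name, delta_f in deltas:
            total = base_f if delta_f is None else base_f + delta_f
            theo = adduct_mz(total, adduct)
            if abs(theo - observed_mz) <= tol_da:
                out.append(
                    ModificationCandidate(
                        base_name, base_f, delta_name, delta_f, adduct, theo, observed_mz
                    )
                )
    out.sort(key=lambda c: (c.abs_error, c.base_name, c.delta_name or ""))
    return out


def explain_fragments(
    parent: Formula,
    parent_adduct: str,
    fragment_mzs: list[float],
    loss_library: list[tuple[str, Formula]],
    tol_da: float,
) -> list[FragmentAssignment]:
    """Assign each MS2 fragment to single or depth-2 chained neutral losses.

    Loss combinations whose composition exceeds the parent are skipped;
    fragments with no candidate within ``tol_da`` come back flagged
    unassigned.  For each fragment only candidate assignments within the
    tolerance are returned (best first), plus a single unassigned record
    when nothing matches.
    """
    if tol_da < 0:
        raise ValueError("tol_da must be >= 0")

    combos: list[tuple[tuple[str, ...], Formula]] = []
    for i, (name_i, f_i) in enumerate(loss_library):
        combos.append(((name_i,), f_i))
        for name_j, f_j in loss_library[i:]:
            combos.append(((name_i, name_j), f_i + f_j))

    out: list[FragmentAssignment] = []
    for mz in fragment_mzs:
        hits = []
        for names, loss_f in combos:
            if not parent.contains(loss_f):
                continue
            remaining = parent - loss_f
            theo = adduct_mz(remaining, parent_adduct)
            err = abs(theo - mz)
            if err <= tol_da:
                hits.append(FragmentAssignment(mz, names, remaining, theo, err, True))
        if hits:
            hits.sort(key=lambda h: (h.abs_error, h.losses))
            out.extend(hits)
        else:
            out.append(FragmentAssignment(mz, (), None, None, None, False))
    return out


def load_library(mapping: dict[str, str]) -> list[tuple[str, Formula]]:
    """Turn a name -> formula-string config mapping into a library list."""
    return [(name, Formula.parse(f)) for name, f in mapping.items()]
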