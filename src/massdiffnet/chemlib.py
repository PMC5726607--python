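"""Chemical transformations, adduct specifications and exact mass arithmetic.

Transformations are named monoisotopic mass deltas (e.g. CH2, H2O) used to
connect peak pairs whose mass difference matches a plausible chemical change.
Adducts are hypotheses of the form [nM+X]z± relating a neutral molecule of
mass M to the m/z actually observed by the instrument:

    m/z = (n * M + offset) / z

where ``offset`` is the summed monoisotopic mass of the attached (or lost)
parts, corrected for the electrons removed or added by the charge.  Working
at sub-ppm accuracy requires the electron correction: the proton [M+H]+ adds
1.007276 Da, not the hydrogen atom's 1.007825 Da.

The built-in transformation and adduct tables are reconstructions assembled
from commonly encountered LC-MS chemistry (alkyl chain extension, hydration,
carbonyl/carboxyl losses, phosphorylation, sulphation, amino-acid transfers,
and the usual positive/negative-mode adducts including dimers, trimers and
doubly charged species).  All deltas and offsets are computed at import time
from the atomic monoisotopic mass table below, never hard-coded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

# Monoisotopic masses of the most abundant isotope, Da (IUPAC/CODATA).
ATOMIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "K": 38.9637064864,
}

#: Rest mass of the electron, Da.
ELECTRON_MASS: float = 0.00054858

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of a molecular formula such as ``C6H14N4O2``.

    Raises :class:`ParseError` for unknown element symbols or stray text.
    """
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ParseError(f"cannot parse formula {formula!r} at position {pos}")
        if not match.group(0):
            break
        symbol, count = match.group(1), match.group(2)
        if symbol not in ATOMIC_MASS:
            raise ParseError(f"unknown element {symbol!r} in formula {formula!r}")
        total += ATOMIC_MASS[symbol] * (int(count) if count else 1)
        pos = match.end()
    if pos != len(formula) or not formula:
        raise ParseError(f"cannot parse formula {formula!r}")
    return total


@dataclass(frozen=True)
class Transformation:
    """A named chemical mass change used to draw transformation edges.

    ``delta_mass`` is always positive; direction is carried by edge
    orientation (low mass -> high mass), so a loss is simply read against
    the arrow.
    """

    name: str
    delta_mass: float
    formula: str | None = None
    type_class: str | None = None

    def __post_init__(self) -> None:
        if self.delta_mass <= 0:
            raise ValidationError(
                f"transformation {self.name!r} has non-positive delta {self.delta_mass}"
            )


# (name, formula, type_class) — deltas derived from ATOMIC_MASS at import.
# The amino-acid entries use residue formulas (loss of water on transfer);
# glucose-N-phosphate uses the glucosyl-phosphate moiety C6H11O8P and
# diphosphate the pyrophosphoryl group H2P2O6 (two condensed HPO3 units).
_DEFAULT_TRANSFORMS: list[tuple[str, str, str]] = [
    ("CH2", "CH2", "alkyl"),
    ("C2H2", "C2H2", "alkyl"),
    ("H2O", "H2O", "hydration"),
    ("CO", "CO", "carbonyl"),
    ("CO2", "CO2", "carboxyl"),
    ("NH3", "NH3", "amine"),
    ("O", "O", "oxidation"),
    ("HPO3", "HPO3", "phosphorylation"),
    ("SO3", "SO3", "sulphation"),
    ("methionine", "C5H9NOS", "amino-acid"),
    ("diphosphate", "H2P2O6", "phosphorylation"),
    ("glucose-N-phosphate", "C6H11O8P", "glycosylation"),
    ("glyoxalate", "C2H2O3", "carboxyl"),
]


def default_transformations() -> list[Transformation]:
    """Built-in transformation list with formula-derived deltas."""
    return [
        Transformation(name=n, delta_mass=formula_mass(f), formula=f, type_class=c)
        for n, f, c in _DEFAULT_TRANSFORMS
    ]


@dataclass(frozen=True)
class AdductSpec:
    """An adduct hypothesis: n copies of M, charge z, signed mass offset.

    ``offset_mass`` is the total mass added to n*M, already corrected for
    the electrons implied by ``z`` and ``polarity``; the observed m/z is
    ``(n * M + offset_mass) / z``.
    """

    name: str
    n: int
    z: int
    polarity: str  # "+" or "-"
    offset_mass: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"adduct {self.name!r}: multimer count must be >= 1")
        if self.z < 1:
            raise ValidationError(f"adduct {self.name!r}: charge must be >= 1")
        if self.polarity not in ("+", "-"):
            raise ValidationError(f"adduct {self.name!r}: polarity must be '+' or '-'")


# Named parts usable in adduct notation; masses from formulas.
_PART_FORMULA: dict[str, str] = {
    "H": "H",
    "Na": "Na",
    "K": "K",
    "Cl": "Cl",
    "NH4": "NH4",
    "ACN": "C2H3N",       # acetonitrile
    "HCOO": "CHO2",       # formate
    "HCOOH": "CH2O2",     # formic acid
    "CH3OH": "CH4O",      # methanol
    "H2O": "H2O",
}

PART_MASS: dict[str, float] = {k: formula_mass(v) for k, v in _PART_FORMULA.items()}

_NOTATION = re.compile(
    r"^\[?(?P<n>\d*)M(?P<parts>(?:[+\-−][A-Za-z0-9]+)*)\]?"
    r"(?P<z>\d*)(?P<zsign>[+\-−]?)$"
)
_PART = re.compile(r"([+\-−])(\d*)([A-Za-z][A-Za-z0-9]*)")


def parse_adduct_notation(
    text: str, polarity: str, charge: int | None = None
) -> AdductSpec:
    """Parse community adduct notation like ``[2M+Na]+`` or ``M-H``.

    The grammar is ``[nM±parts]z±``: an optional multimer count ``n``
    (default 1), one or more signed part tokens drawn from the named-part
    table (H, Na, K, NH4, ACN, HCOO, Cl, ...; a leading digit repeats the
    part, as in ``+2H``), and an optional trailing charge count (default 1).
    ``charge`` overrides the parsed charge when given.  The electron
    correction (z electrons removed in positive mode, added in negative)
    is folded into ``offset_mass``.
    """
    if polarity not in ("+", "-"):
        raise ValidationError(f"polarity must be '+' or '-', got {polarity!r}")
    match = _NOTATION.match(text.strip())
    if match is None:
        raise ParseError(f"cannot parse adduct notation {text!r}")
    n = int(match.group("n")) if match.group("n") else 1
    z = int(match.group("z")) if match.group("z") else 1
    if charge is not None:
        z = charge
    if z == 0:
        raise ValidationError(f"adduct {text!r}: charge count cannot be 0")

    parts_text = match.group("parts")
    offset = 0.0
    pos = 0
    for pm in _PART.finditer(parts_text):
        if pm.start() != pos:
            raise ParseError(f"cannot parse adduct parts in {text!r}")
        sign = -1.0 if pm.group(1) in ("-", "−") else 1.0
        count = int(pm.group(2)) if pm.group(2) else 1
        token = pm.group(3)
        if token not in PART_MASS:
            raise ParseError(f"unknown adduct part {token!r} in {text!r}")
        offset += sign * count * PART_MASS[token]
        pos = pm.end()
    if pos != len(parts_text):
        raise ParseError(f"cannot parse adduct parts in {text!r}")

    electron_sign = -1.0 if polarity == "+" else 1.0
    offset += electron_sign * z * ELECTRON_MASS
    return AdductSpec(name=text.strip(), n=n, z=z, polarity=polarity, offset_mass=offset)


def predicted_mass(M: float, spec: AdductSpec) -> float:
    """Observed m/z predicted for a neutral molecule of mass ``M`` under ``spec``."""
    if M <= 0:
        raise ValidationError(f"neutral mass must be positive, got {M}")
    result = (spec.n * M + spec.offset_mass) / spec.z
    if result <= 0:
        raise ValidationError(
            f"adduct {spec.name!r} predicts non-positive mass for M={M}"
        )
    return result


def invert_predicted_mass(m_obs: float, spec: AdductSpec) -> float | None:
    """Neutral mass implied by an observed m/z under ``spec``.

    Exact inverse of :func:`predicted_mass`.  Returns None when the implied
    neutral mass is non-positive (no hypothesis: the caller skips this spec).
    """
    if m_obs <= 0:
        raise ValidationError(f"observed mass must be positive, got {m_obs}")
    M = (spec.z * m_obs - spec.offset_mass) / spec.n
    return M if M > 0 else None


IDENTITY_ADDUCT = AdductSpec(name="M", n=1, z=1, polarity="+", offset_mass=0.0)

_DEFAULT_ADDUCT_NOTATIONS: list[tuple[str, str]] = [
    ("[M+H]+", "+"),
    ("[M+Na]+", "+"),
    ("[M+K]+", "+"),
    ("[M+NH4]+", "+"),
    ("[M+ACN+H]+", "+"),
    ("[2M+H]+", "+"),
    ("[2M+Na]+", "+"),
    ("[3M+H]+", "+"),
    ("[M+2H]2+", "+"),
    ("[M-H]-", "-"),
    ("[M+Cl]-", "-"),
    ("[M+HCOO]-", "-"),
    ("[2M-H]-", "-"),
]


def default_adducts(polarity: str | None = None) -> list[AdductSpec]:
    """Built-in adduct table; optionally restricted to one polarity."""
    specs = [parse_adduct_notation(t, p) for t, p in _DEFAULT_ADDUCT_NOTATIONS]
    if polarity is not None:
        specs = [s for s in specs if s.polarity == polarity]
    return specs


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a headered TSV, falling back to comma when the header has no tab."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_transformations(path: str | Path) -> list[Transformation]:
    """Read a transformation table (columns: name, delta_mass; optional
    formula, type_class) in file order at full precision."""
    df = _read_delimited(path)
    for col in ("name", "delta_mass"):
        if col not in df.columns:
            raise ValidationError(f"transformation table {path} lacks column {col!r}")
    out: list[Transformation] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        name = row["name"].strip()
        if name in seen:
            raise ValidationError(f"duplicate transformation name {name!r}")
        seen.add(name)
        try:
            delta = float(row["delta_mass"])
        except ValueError as exc:
            raise ParseError(
                f"non-numeric delta_mass {row['delta_mass']!r} at row {i + 1}"
            ) from exc
        if delta <= 0:
            raise ValidationError(
                f"transformation {name!r} has non-positive delta {delta}"
            )
        formula = row.get("formula", "") or None
        type_class = row.get("type_class", "") or None
        out.append(Transformation(name, delta, formula, type_class))
    return out


def read_adducts(path: str | Path) -> list[AdductSpec]:
    """Read an adduct table (columns: name, polarity; optional explicit
    n, z, offset_mass overriding the values parsed from the notation)."""
    df = _read_delimited(path)
    for col in ("name", "polarity"):
        if col not in df.columns:
            raise ValidationError(f"adduct table {path} lacks column {col!r}")
    out: list[AdductSpec] = []
    for _, row in df.iterrows():
        spec = parse_adduct_notation(row["name"], row["polarity"].strip())
        n = int(row["n"]) if row.get("n", "") else spec.n
        z = int(row["z"]) if row.get("z", "") else spec.z
        offset = float(row["offset_mass"]) if row.get("offset_mass", "") else spec.offset_mass
        out.append(AdductSpec(spec.name, n, z, spec.polarity, offset))
    return out


def write_transformations(transforms: Iterable[Transformation], path: str | Path) -> None:
    rows = [
        {
            "name": t.name,
            "formula": t.formula or "",
            "delta_mass": repr(t.delta_mass),
            "type_class": t.type_class or "",
        }
        for t in transforms
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def transformations_by_name(transforms: Sequence[Transformation]) -> dict[str, Transformation]:
    return {t.name: t for t in transforms}
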