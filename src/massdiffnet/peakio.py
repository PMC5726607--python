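"""Reading, validation and writing of delimited peak tables.

A peak table is a headered TSV (comma accepted, auto-detected from the
header line) with one row per detected MS feature: an optional identifier
column, a required mass column (Da; neutral mass or m/z — interpretation is
deferred to the adduct matcher's ``mass_type`` flag), an optional retention
time column (seconds), and any number of additional numeric columns headed
by a sample label and holding abundances.  Empty abundance cells mean "not
measured", which is distinct from zero: an absent value can never satisfy an
intensity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError


@dataclass
class Peak:
    """One detected MS feature."""

    peak_id: str
    mass: float
    rt: float | None = None
    abundances: dict[str, float] = field(default_factory=dict)


@dataclass
class PeakTable:
    """An ordered collection of peaks plus the sample labels they carry."""

    peaks: list[Peak]
    samples: list[str]
    source: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    def by_id(self) -> dict[str, Peak]:
        return {p.peak_id: p for p in self.peaks}

    def masses(self) -> list[float]:
        return [p.mass for p in self.peaks]


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_peak_table(
    path: str | Path,
    mass_column: str = "mass",
    rt_column: str | None = None,
    id_column: str | None = None,
) -> PeakTable:
    """Read a delimited peak table.

    Every column other than the id, mass and rt columns whose non-empty
    cells all parse as numbers becomes a sample abundance column;
    non-numeric columns (annotations etc.) are ignored.  When no id column
    is given, ids are synthesized from the mass formatted to 4 decimals,
    with a row-index suffix on collision.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"peak table not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    if mass_column not in df.columns:
        raise ConfigurationError(
            f"mass column {mass_column!r} not in header {list(df.columns)}"
        )
    if rt_column is not None and rt_column not in df.columns:
        raise ConfigurationError(f"rt column {rt_column!r} not in header")
    if id_column is not None and id_column not in df.columns:
        raise ConfigurationError(f"id column {id_column!r} not in header")

    reserved = {mass_column, rt_column, id_column} - {None}
    sample_cols: list[str] = []
    for col in df.columns:
        if col in reserved:
            continue
        cells = [c for c in df[col] if c.strip() != ""]
        if not cells:
            continue
        try:
            for c in cells:
                float(c)
        except ValueError:
            continue  # annotation column, not abundances
        sample_cols.append(col)

    peaks: list[Peak] = []
    seen_ids: set[str] = set()
    for i, row in df.iterrows():
        rownum = int(i) + 1  # 1-based data row, not counting the header
        raw_mass = row[mass_column].strip()
        try:
            mass = float(raw_mass)
        except ValueError as exc:
            raise ParseError(
                f"non-numeric mass {raw_mass!r} at row {rownum} of {path.name}"
            ) from exc
        if mass <= 0:
            raise ValidationError(f"non-positive mass {mass} at row {rownum}")

        rt: float | None = None
        if rt_column is not None:
            raw_rt = row[rt_column].strip()
            if raw_rt != "":
                try:
                    rt = float(raw_rt)
                except ValueError as exc:
                    raise ParseError(
                        f"non-numeric rt {raw_rt!r} at row {rownum}"
                    ) from exc

        if id_column is not None:
            peak_id = row[id_column].strip()
            if peak_id in seen_ids:
                raise ValidationError(f"duplicate peak id {peak_id!r} at row {rownum}")
        else:
            peak_id = f"{mass:.4f}"
            if peak_id in seen_ids:
                peak_id = f"{mass:.4f}_r{int(i)}"
        seen_ids.add(peak_id)

        abundances: dict[str, float] = {}
        for col in sample_cols:
            cell = row[col].strip()
            if cell != "":
                abundances[col] = float(cell)
        peaks.append(Peak(peak_id=peak_id, mass=mass, rt=rt, abundances=abundances))

    return PeakTable(peaks=peaks, samples=sample_cols, source=str(path))


def write_peak_table(table: PeakTable, path: str | Path, sep: str = "\t") -> None:
    """Write a peak table with columns id, mass, rt (if any), then samples.

    Floats are written with ``repr`` so a read-back reproduces every value
    bit-for-bit.
    """
    has_rt = any(p.rt is not None for p in table.peaks)
    rows = []
    for p in table.peaks:
        row: dict[str, str] = {"id": p.peak_id, "mass": repr(p.mass)}
        if has_rt:
            row["rt"] = repr(p.rt) if p.rt is not None else ""
        for s in table.samples:
            row[s] = repr(p.abundances[s]) if s in p.abundances else ""
        rows.append(row)
    cols = ["id", "mass"] + (["rt"] if has_rt else []) + list(table.samples)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=sep, index=False)


def validate_peak_table(table: PeakTable) -> list[str]:
    """Return human-readable messages for every violated invariant.

    An empty list means the table is well-formed.
    """
    messages: list[str] = []
    seen: dict[str, int] = {}
    for p in table.peaks:
        seen[p.peak_id] = seen.get(p.peak_id, 0) + 1
        if p.mass <= 0:
            messages.append(f"peak {p.peak_id!r}: mass {p.mass} is not positive")
        if p.rt is not None and p.rt < 0:
            messages.append(f"peak {p.peak_id!r}: negative rt {p.rt}")
        for s, a in p.abundances.items():
            if a < 0:
                messages.append(
                    f"peak {p.peak_id!r}: negative abundance {a} in sample {s!r}"
                )
            if s not in table.samples:
                messages.append(
                    f"peak {p.peak_id!r}: abundance for unknown sample {s!r}"
                )
    for pid, count in seen.items():
        if count > 1:
            messages.append(f"duplicate peak id {pid!r} ({count} occurrences)")
    return messages
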