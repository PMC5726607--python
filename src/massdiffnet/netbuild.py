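"""Core matching: transformation-edge and adduct-edge discovery.

Transformation matching connects every pair of peaks whose mass difference
equals a listed transformation delta within a mass tolerance; the ppm
reference is the heavier peak, because instrument error scales with measured
mass.  Adduct matching assumes each peak in turn is the base ion (typically
[M+H]+ or [M-H]-), infers the neutral mass, predicts the m/z of every other
adduct hypothesis and links peaks landing within tolerance of a prediction.
Both searches accept an optional retention-time window so that only
co-eluting features are linked (10 s is the canonical setting for adducts).

Candidate pairs are found by a sorted two-pointer sweep over the mass axis,
O(n log n + T·n + matches), never materialising all n^2 pairs; a brute-force
double loop over small instances serves as the reference oracle in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemlib import (
    AdductSpec,
    IDENTITY_ADDUCT,
    Transformation,
    invert_predicted_mass,
    parse_adduct_notation,
    predicted_mass,
)
from .errors import ConfigurationError, IntegrityError, ValidationError
from .peakio import Peak, PeakTable


@dataclass(frozen=True)
class Tolerance:
    """Mass-match tolerance, in ppm of a reference mass or in mDa.

    Acceptance is inclusive: an error exactly at the window boundary matches.
    """

    mode: str  # "ppm" | "mda"
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("ppm", "mda"):
            raise ValidationError(f"tolerance mode must be 'ppm' or 'mda', got {self.mode!r}")
        if self.value <= 0:
            raise ValidationError(f"tolerance value must be positive, got {self.value}")

    def window(self, reference_mass: float) -> float:
        """Half-width of the acceptance window in Da at ``reference_mass``."""
        if self.mode == "ppm":
            return self.value * 1e-6 * reference_mass
        return self.value / 1000.0

    def accepts(self, observed: float, expected: float, reference_mass: float) -> bool:
        return abs(observed - expected) <= self.window(reference_mass)


@dataclass(frozen=True)
class MatchEdge:
    """A scored link between two peaks.

    ``source_id`` is always the lower-mass endpoint.  For transform edges,
    ``observed_delta`` is the measured mass difference and ``expected_value``
    the transformation delta; for adduct edges, ``observed_delta`` is the
    measured mass of the matched peak and ``expected_value`` the predicted
    adduct m/z.  ``error_ppm`` is signed, (observed - expected) / reference.
    """

    source_id: str
    target_id: str
    kind: str  # "transform" | "adduct"
    label: str
    observed_delta: float
    expected_value: float
    error_ppm: float
    rt_delta: float | None = None
    type_class: str | None = None


@dataclass
class MassDiffNetwork:
    """Peaks as nodes, matched relations as (possibly parallel) labelled edges."""

    peaks: list[Peak]
    edges: list[MatchEdge]
    params: dict = field(default_factory=dict)
    samples: list[str] = field(default_factory=list)

    @property
    def node_ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]

    def peak_by_id(self) -> dict[str, Peak]:
        return {p.peak_id: p for p in self.peaks}


def _sorted_arrays(table: PeakTable):
    masses = np.array([p.mass for p in table.peaks], dtype=float)
    order = np.argsort(masses, kind="stable")
    return masses[order], [table.peaks[i] for i in order]


def _require_rt(table: PeakTable) -> None:
    for p in table.peaks:
        if p.rt is None:
            raise ConfigurationError(
                f"rt window requested but peak {p.peak_id!r} has no retention time"
            )


def find_transformation_edges(
    table: PeakTable,
    transforms: Sequence[Transformation],
    tol: Tolerance,
    rt_window: float | None = None,
) -> list[MatchEdge]:
    """All (peak pair, transformation) matches within tolerance.

    A pair matching k transformations yields k parallel edges — ambiguity is
    information, not noise.  Edges are oriented low mass -> high mass and the
    result is sorted by (source_id, target_id, label), so the output is
    independent of input row order.
    """
    if not transforms:
        raise ConfigurationError("transformation list is empty")
    if rt_window is not None:
        _require_rt(table)
    if len(table.peaks) < 2:
        return []

    masses, peaks = _sorted_arrays(table)
    n = len(peaks)
    edges: list[MatchEdge] = []
    max_mass = float(masses[-1])

    for t in transforms:
        # conservative search half-width: the exact window depends on the
        # heavier peak, bounded above by the window at the table maximum
        wmax = tol.window(max_mass) if tol.mode == "ppm" else tol.window(0.0)
        expected = masses + t.delta_mass
        lo_idx = np.searchsorted(masses, expected - wmax, side="left")
        hi_idx = np.searchsorted(masses, expected + wmax, side="right")
        for i in range(n):
            for j in range(int(lo_idx[i]), int(hi_idx[i])):
                if j == i:
                    continue
                m_lo, m_hi = masses[i], masses[j]
                if m_hi <= m_lo:
                    continue
                observed = float(m_hi - m_lo)
                if not tol.accepts(observed, t.delta_mass, float(m_hi)):
                    continue
                p_lo, p_hi = peaks[i], peaks[j]
                rt_delta = None
                if p_lo.rt is not None and p_hi.rt is not None:
                    rt_delta = abs(p_hi.rt - p_lo.rt)
                if rt_window is not None and rt_delta > rt_window:
                    continue
                edges.append(
                    MatchEdge(
                        source_id=p_lo.peak_id,
                        target_id=p_hi.peak_id,
                        kind="transform",
                        label=t.name,
                        observed_delta=observed,
                        expected_value=t.delta_mass,
                        error_ppm=(observed - t.delta_mass) / m_hi * 1e6,
                        rt_delta=rt_delta,
                        type_class=t.type_class,
                    )
                )
    edges.sort(key=lambda e: (e.source_id, e.target_id, e.label))
    return edges


def _default_base_spec(mass_type: str) -> AdductSpec:
    if mass_type == "neutral":
        return IDENTITY_ADDUCT
    if mass_type == "mz_positive":
        return parse_adduct_notation("[M+H]+", "+")
    if mass_type == "mz_negative":
        return parse_adduct_notation("[M-H]-", "-")
    raise ConfigurationError(
        f"mass_type must be neutral, mz_positive or mz_negative, got {mass_type!r}"
    )


def find_adduct_edges(
    table: PeakTable,
    adducts: Sequence[AdductSpec],
    tol: Tolerance,
    rt_window: float | None = None,
    mass_type: str = "neutral",
    base_spec: AdductSpec | None = None,
) -> list[MatchEdge]:
    """Adduct-edge discovery around candidate base-ion peaks.

    Every peak is tried as the base ion: its neutral mass is inferred through
    ``base_spec`` (defaults: identity for neutral masses, [M+H]+ / [M-H]- for
    positive / negative m/z), the observed mass of every other adduct
    hypothesis is predicted, and peaks within tolerance (ppm reference = the
    predicted mass) and inside the rt window of the base are linked to it.
    The base spec itself is never emitted as a label and a peak is never
    linked to itself.
    """
    if base_spec is None:
        base_spec = _default_base_spec(mass_type)
    if mass_type == "mz_positive":
        bad = [a.name for a in adducts if a.polarity != "+"]
        if bad:
            raise ConfigurationError(f"negative-mode adducts {bad} with mass_type mz_positive")
    elif mass_type == "mz_negative":
        bad = [a.name for a in adducts if a.polarity != "-"]
        if bad:
            raise ConfigurationError(f"positive-mode adducts {bad} with mass_type mz_negative")
    elif mass_type != "neutral":
        raise ConfigurationError(f"unknown mass_type {mass_type!r}")
    if rt_window is not None:
        _require_rt(table)
    if len(table.peaks) < 2:
        return []

    masses, peaks = _sorted_arrays(table)
    specs = [
        a
        for a in adducts
        if not (
            a.n == base_spec.n
            and a.z == base_spec.z
            and a.polarity == base_spec.polarity
            and abs(a.offset_mass - base_spec.offset_mass) < 1e-12
        )
    ]
    edges: dict[tuple[str, str, str], MatchEdge] = {}

    for bi, base in enumerate(peaks):
        M = invert_predicted_mass(float(masses[bi]), base_spec)
        if M is None:
            continue
        for spec in specs:
            try:
                expected = predicted_mass(M, spec)
            except ValidationError:
                continue
            w = tol.window(expected)
            lo = int(np.searchsorted(masses, expected - w, side="left"))
            hi = int(np.searchsorted(masses, expected + w, side="right"))
            for j in range(lo, hi):
                if j == bi:
                    continue
                if not tol.accepts(float(masses[j]), expected, expected):
                    continue
                other = peaks[j]
                rt_delta = None
                if base.rt is not None and other.rt is not None:
                    rt_delta = abs(base.rt - other.rt)
                if rt_window is not None and rt_delta > rt_window:
                    continue
                if base.mass <= other.mass:
                    src, tgt = base, other
                else:
                    src, tgt = other, base
                key = (src.peak_id, tgt.peak_id, spec.name)
                if key in edges:
                    continue
                edges[key] = MatchEdge(
                    source_id=src.peak_id,
                    target_id=tgt.peak_id,
                    kind="adduct",
                    label=spec.name,
                    observed_delta=float(masses[j]),
                    expected_value=expected,
                    error_ppm=(float(masses[j]) - expected) / expected * 1e6,
                    rt_delta=rt_delta,
                )
    out = list(edges.values())
    out.sort(key=lambda e: (e.source_id, e.target_id, e.label))
    return out


def build_network(
    table: PeakTable,
    edges: Sequence[MatchEdge],
    keep_orphans: bool = True,
    params: dict | None = None,
) -> MassDiffNetwork:
    """Assemble peaks and matched edges into a network.

    ``keep_orphans=False`` drops peaks with no incident edge.  Every edge
    endpoint must exist in the table.
    """
    ids = {p.peak_id for p in table.peaks}
    for e in edges:
        for endpoint in (e.source_id, e.target_id):
            if endpoint not in ids:
                raise IntegrityError(f"edge endpoint {endpoint!r} not in peak table")
    if keep_orphans:
        peaks = list(table.peaks)
    else:
        used = {e.source_id for e in edges} | {e.target_id for e in edges}
        peaks = [p for p in table.peaks if p.peak_id in used]
    return MassDiffNetwork(
        peaks=peaks,
        edges=list(edges),
        params=dict(params or {}),
        samples=list(table.samples),
    )
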