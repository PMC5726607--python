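"""Synthetic peak tables with planted structure and recorded ground truth.

The generator emulates the feature lists a high-resolution LC-MS run
produces: compounds whose masses form chains under chemical transformations
(the grid-like lipid patterns of chain extension x hydroxylation), adduct
satellites predicted from the neutral mass, log-normally distributed
abundances across samples with an optional multiplicative group effect on
the transformed partner of one label, Gaussian ppm mass noise, and decoy
peaks rejection-sampled so that no decoy sits near any valid transformation
or adduct relation — a clean negative control for precision tests.

Beyond the decoys, every planted mass is itself checked against all
previously emitted peaks: a chain or satellite whose *unplanned* pairwise
mass differences collide with a transformation delta (within the exclusion
window) is resampled, so the recorded truth is the complete set of valid
relations at the tested tolerance, not merely a subset.

Everything is driven by one integer seed through numpy's Generator, so a
given config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chemlib import AdductSpec, Transformation, default_transformations, predicted_mass
from .errors import GenerationError
from .peakio import Peak, PeakTable

_MAX_TRIES = 2000


def _default_chain_transforms() -> list[Transformation]:
    wanted = ("CH2", "C2H2", "H2O", "CO", "NH3")
    by_name = {t.name: t for t in default_transformations()}
    return [by_name[n] for n in wanted]


@dataclass
class SynthConfig:
    """Study conditions for one simulated peak table.

    Defaults describe a modest untargeted metabolomics run: compounds in the
    150-900 Da range, transformation chains of 1-4 steps over five common
    chemical changes, 1 ppm mass noise (a well-calibrated Orbitrap),
    log10 intensities centred on 6 (the 10^5-count intensity regime where
    thresholding is meaningful) with 10% between-sample variation, and two
    groups of four samples.
    """

    n_compounds: int = 60
    mass_range: tuple[float, float] = (150.0, 900.0)
    chain_transforms: list[Transformation] = field(default_factory=_default_chain_transforms)
    chain_length_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.30, 3: 0.25, 4: 0.20}
    )
    adduct_specs: list[AdductSpec] = field(default_factory=list)
    adduct_probability: float = 0.0
    mass_noise_ppm_sd: float = 1.0
    rt_range: tuple[float, float] = (60.0, 900.0)
    rt_jitter_sd: float = 1.0
    n_decoys: int = 0
    decoy_exclusion_ppm: float = 15.0
    samples: tuple[str, ...] = ("A_1", "A_2", "A_3", "A_4", "B_1", "B_2", "B_3", "B_4")
    sample_groups: dict[str, str] = field(
        default_factory=lambda: {
            "A_1": "A", "A_2": "A", "A_3": "A", "A_4": "A",
            "B_1": "B", "B_2": "B", "B_3": "B", "B_4": "B",
        }
    )
    intensity_lognormal: tuple[float, float] = (6.0, 0.5)
    abundance_cv: float = 0.1
    planted_ratio_effect: tuple[str, str, float] | None = None
    seed: int = 0


@dataclass
class SynthTruth:
    """Ground truth recorded before mass noise."""

    transform_edges: list[tuple[str, str, str]]  # (source_id, target_id, label)
    adduct_edges: list[tuple[str, str, str]]
    true_masses: dict[str, float]
    true_abundances: dict[str, dict[str, float]]  # pre sample-noise, post effect


def _conflicts(
    candidates: np.ndarray,
    existing: np.ndarray,
    deltas: np.ndarray,
    exclusion_ppm: float,
    allowed: set[tuple[int, int]] | None = None,
    candidate_offset: int = 0,
) -> bool:
    """True when any candidate/existing pair's |mass difference| lies within
    the ppm exclusion window (reference = heavier mass) of any delta.

    ``allowed`` lists (existing_index, candidate_index + offset) pairs that
    are planted relations and therefore exempt.
    """
    if existing.size == 0 or candidates.size == 0:
        return False
    diff = np.abs(candidates[:, None] - existing[None, :])
    heavier = np.maximum(candidates[:, None], existing[None, :])
    window = exclusion_ppm * 1e-6 * heavier
    for d in deltas:
        hits = np.argwhere(np.abs(diff - d) <= window)
        for ci, ei in hits:
            if allowed and (int(ei), int(ci) + candidate_offset) in allowed:
                continue
            return True
    return False


def _adduct_conflicts(
    candidates: np.ndarray,
    existing: np.ndarray,
    specs: Sequence[AdductSpec],
    exclusion_ppm: float,
    allowed: set[tuple[int, int]] | None = None,
    candidate_offset: int = 0,
) -> bool:
    """True when a candidate sits within the exclusion window of an adduct
    prediction from an existing peak (treated as a neutral mass) or vice
    versa, outside the allowed planted relations."""
    if existing.size == 0 or candidates.size == 0 or not specs:
        return False
    for spec in specs:
        for arr_a, arr_b, flip in ((existing, candidates, True), (candidates, existing, False)):
            pred = (spec.n * arr_a + spec.offset_mass) / spec.z
            ok = pred > 0
            diff = np.abs(arr_b[:, None] - pred[None, :])
            window = exclusion_ppm * 1e-6 * np.maximum(pred[None, :], 1.0)
            hits = np.argwhere((diff <= window) & ok[None, :])
            for bi, ai in hits:
                if flip:
                    pair = (int(ai), int(bi) + candidate_offset)
                else:
                    pair = (int(bi), int(ai) + candidate_offset)
                if allowed and pair in allowed:
                    continue
                return True
    return False


def simulate(config: SynthConfig) -> tuple[PeakTable, SynthTruth]:
    """Generate one peak table plus its ground truth, deterministically.

    Construction order: transformation chains (resampled wholesale when any
    unplanned pairwise relation falls inside the exclusion window), adduct
    satellites, decoys, then abundances and mass noise.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mass_range
    deltas = np.array([t.delta_mass for t in config.chain_transforms], dtype=float)
    lengths = np.array(sorted(config.chain_length_distribution), dtype=int)
    probs = np.array([config.chain_length_distribution[int(k)] for k in lengths])
    probs = probs / probs.sum()

    true_masses_list: list[float] = []
    rts: list[float] = []
    ids: list[str] = []
    transform_truth: list[tuple[str, str, str]] = []
    adduct_truth: list[tuple[str, str, str]] = []
    # planted relations by index into the growing mass list, both orders
    allowed: set[tuple[int, int]] = set()

    def planted(i: int, j: int) -> None:
        allowed.add((i, j))
        allowed.add((j, i))

    for c in range(config.n_compounds):
        for attempt in range(_MAX_TRIES):
            base = float(rng.uniform(lo, hi))
            length = int(rng.choice(lengths, p=probs))
            steps = rng.integers(0, len(deltas), size=length)
            chain = [base]
            for s in steps:
                chain.append(chain[-1] + float(deltas[s]))
            chain_arr = np.array(chain)
            # internal non-adjacent relations must not collide either
            internal_allowed = {
                (k, k + 1) for k in range(length)
            } | {(k + 1, k) for k in range(length)}
            existing = np.array(true_masses_list)
            if _conflicts(
                chain_arr,
                chain_arr,
                deltas,
                config.decoy_exclusion_ppm,
                allowed={(a, b + 0) for a, b in internal_allowed},
            ):
                continue
            if _conflicts(chain_arr, existing, deltas, config.decoy_exclusion_ppm):
                continue
            if _adduct_conflicts(
                chain_arr, existing, config.adduct_specs, config.decoy_exclusion_ppm
            ):
                continue
            break
        else:
            raise GenerationError(
                f"could not place chain {c} outside exclusion windows"
            )
        base_idx = len(true_masses_list)
        rt_chain = [float(rng.uniform(*config.rt_range)) for _ in chain]
        for k, (m, rt) in enumerate(zip(chain, rt_chain)):
            ids.append(f"C{c}_{k}")
            true_masses_list.append(float(m))
            rts.append(rt)
        for k, s in enumerate(steps):
            i, j = base_idx + k, base_idx + k + 1
            planted(i, j)
            transform_truth.append(
                (ids[i], ids[j], config.chain_transforms[int(s)].name)
            )
        # adduct satellites of each chain member (the member itself is the
        # neutral / base-ion reference; satellites co-elute with it)
        for k in range(len(chain)):
            member_idx = base_idx + k
            for spec in config.adduct_specs:
                if rng.random() >= config.adduct_probability:
                    continue
                sat = predicted_mass(chain[k], spec)
                sat_arr = np.array([sat])
                existing = np.array(true_masses_list)
                if _conflicts(sat_arr, existing, deltas, config.decoy_exclusion_ppm):
                    continue
                if _adduct_conflicts(
                    sat_arr,
                    existing,
                    config.adduct_specs,
                    config.decoy_exclusion_ppm,
                    allowed={(member_idx, len(true_masses_list))},
                    candidate_offset=len(true_masses_list),
                ):
                    continue
                sat_idx = len(true_masses_list)
                sat_id = f"C{c}_{k}_{spec.name}"
                ids.append(sat_id)
                true_masses_list.append(float(sat))
                rts.append(rts[member_idx] + float(rng.normal(0, config.rt_jitter_sd)))
                planted(member_idx, sat_idx)
                pair = (ids[member_idx], sat_id)
                if sat >= chain[k]:
                    adduct_truth.append((pair[0], pair[1], spec.name))
                else:
                    adduct_truth.append((pair[1], pair[0], spec.name))

    span = hi - lo + (lengths.max() if lengths.size else 0) * (
        float(deltas.max()) if deltas.size else 0.0
    )
    for d in range(config.n_decoys):
        for attempt in range(_MAX_TRIES):
            m = float(rng.uniform(lo, lo + span))
            existing = np.array(true_masses_list)
            if _conflicts(np.array([m]), existing, deltas, config.decoy_exclusion_ppm):
                continue
            if _adduct_conflicts(
                np.array([m]), existing, config.adduct_specs, config.decoy_exclusion_ppm
            ):
                continue
            break
        else:
            raise GenerationError(f"could not place decoy {d} outside exclusion windows")
        ids.append(f"D{d}")
        true_masses_list.append(m)
        rts.append(float(rng.uniform(*config.rt_range)))

    true_masses = np.array(true_masses_list)

    # abundances: per-peak log-normal base intensity, optional group effect
    # on the heavier (transformed) partner of one label, then per-sample
    # multiplicative noise
    mean_log10, sd_log10 = config.intensity_lognormal
    base_intensity = 10.0 ** rng.normal(mean_log10, sd_log10, size=len(ids))
    effect_ids: set[str] = set()
    if config.planted_ratio_effect is not None:
        label, group, mult = config.planted_ratio_effect
        effect_ids = {tgt for _, tgt, lab in transform_truth if lab == label}
    true_abund: dict[str, dict[str, float]] = {}
    obs_abund: dict[str, dict[str, float]] = {}
    for idx, pid in enumerate(ids):
        true_abund[pid] = {}
        obs_abund[pid] = {}
        for s in config.samples:
            value = float(base_intensity[idx])
            if config.planted_ratio_effect is not None and pid in effect_ids:
                label, group, mult = config.planted_ratio_effect
                if config.sample_groups.get(s) == group:
                    value *= mult
            true_abund[pid][s] = value
            noisy = value * float(np.exp(rng.normal(0, config.abundance_cv)))
            obs_abund[pid][s] = noisy

    observed = true_masses * (
        1.0 + rng.normal(0, config.mass_noise_ppm_sd * 1e-6, size=len(ids))
    )

    peaks = [
        Peak(
            peak_id=pid,
            mass=float(observed[i]),
            rt=rts[i],
            abundances=obs_abund[pid],
        )
        for i, pid in enumerate(ids)
    ]
    table = PeakTable(peaks=peaks, samples=list(config.samples), source="synthetic")
    truth = SynthTruth(
        transform_edges=transform_truth,
        adduct_edges=adduct_truth,
        true_masses={pid: float(true_masses[i]) for i, pid in enumerate(ids)},
        true_abundances=true_abund,
    )
    return table, truth


def grid_fixture() -> tuple[PeakTable, SynthTruth]:
    """Deterministic 4x3 grid: +C2H2 steps across columns, +O steps down
    rows, from base mass 200 — the lipid chain-extension x hydroxylation
    pattern.  12 noiseless peaks, 17 truth edges (9 horizontal + 8 vertical),
    all co-eluting."""
    by_name = {t.name: t for t in default_transformations()}
    c2h2 = by_name["C2H2"].delta_mass
    oxy = by_name["O"].delta_mass
    peaks: list[Peak] = []
    truth: list[tuple[str, str, str]] = []
    masses: dict[tuple[int, int], float] = {}
    for r in range(3):
        for c in range(4):
            m = 200.0 + c * c2h2 + r * oxy
            pid = f"g{r}{c}"
            masses[(r, c)] = m
            peaks.append(Peak(peak_id=pid, mass=m, rt=300.0))
    for r in range(3):
        for c in range(3):
            truth.append((f"g{r}{c}", f"g{r}{c + 1}", "C2H2"))
    for r in range(2):
        for c in range(4):
            truth.append((f"g{r}{c}", f"g{r + 1}{c}", "O"))
    table = PeakTable(peaks=peaks, samples=[], source="grid_fixture")
    return table, SynthTruth(
        transform_edges=truth,
        adduct_edges=[],
        true_masses={p.peak_id: p.mass for p in peaks},
        true_abundances={},
    )


def write_truth(truth: SynthTruth, path: str | Path) -> None:
    """Edge-list TSV of the planted relations, for external harnesses."""
    rows = [
        {"source": s, "target": t, "label": l, "kind": "transform"}
        for s, t, l in truth.transform_edges
    ] + [
        {"source": s, "target": t, "label": l, "kind": "adduct"}
        for s, t, l in truth.adduct_edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "label", "kind"]).to_csv(
        path, sep="\t", index=False
    )
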