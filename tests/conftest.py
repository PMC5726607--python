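import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from massdiffnet.peakio import Peak, PeakTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_table(masses, rts=None, abundances=None, samples=None, ids=None):
    """Build a PeakTable from parallel lists; abundances is a list of dicts."""
    peaks = []
    for i, m in enumerate(masses):
        peaks.append(
            Peak(
                peak_id=ids[i] if ids else f"P{i}",
                mass=float(m),
                rt=None if rts is None else float(rts[i]),
                abundances=dict(abundances[i]) if abundances else {},
            )
        )
    if samples is None:
        samples = sorted({s for p in peaks for s in p.abundances})
    return PeakTable(peaks=peaks, samples=list(samples), source="test")


def brute_force_transform_edges(table, transforms, tol, rt_window=None):
    """Reference oracle: dumb double loop over all pairs and transformations.

    Returns the set of (source_id, target_id, label) triples with the same
    orientation and acceptance rules as the sweep implementation.
    """
    out = set()
    peaks = table.peaks
    for i in range(len(peaks)):
        for j in range(len(peaks)):
            lo, hi = peaks[i], peaks[j]
            if hi.mass <= lo.mass:
                continue
            if rt_window is not None and abs(hi.rt - lo.rt) > rt_window:
                continue
            observed = hi.mass - lo.mass
            for t in transforms:
                if abs(observed - t.delta_mass) <= tol.window(hi.mass):
                    out.add((lo.peak_id, hi.peak_id, t.name))
    return out


def random_instance(seed, n=100, transforms=None, planted_fraction=0.4):
    """Random peak table mixing uniform masses with near-delta pairs so the
    tolerance boundary is actually exercised."""
    rng = np.random.default_rng(seed)
    masses = list(rng.uniform(100.0, 1000.0, size=max(1, int(n * (1 - planted_fraction)))))
    deltas = [t.delta_mass for t in transforms]
    while len(masses) < n:
        base = masses[int(rng.integers(0, len(masses)))]
        d = deltas[int(rng.integers(0, len(deltas)))]
        jitter_ppm = rng.uniform(-8.0, 8.0)
        masses.append((base + d) * (1.0 + jitter_ppm * 1e-6))
    rts = rng.uniform(0.0, 600.0, size=n)
    return make_table(masses, rts=rts)


@pytest.fixture
def frag_table():
    """The three-fragment spectrum used as a worked example: a base fragment
    at 84.0443 linked by CH2 to 98.0599 below the 180.09 precursor."""
    return make_table([84.0443, 98.0599, 180.0900])
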