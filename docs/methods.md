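# Methods

## The model

High-resolution MS feature lists contain far more structure than a flat
table of masses suggests. Two features may be substrate and product of the
same chemical reaction, in which case their mass difference equals the
monoisotopic mass change of that reaction up to instrument error; or they
may be technological images of the same molecule — adducts, multimers,
multi-charge species — in which case their masses satisfy

    m/z = (n · M + offset) / z

for a neutral mass M, multimer count n, charge z and an offset summing the
attached parts and the electron correction. `massdiffnet` builds networks
directly from these two relations, without reference to any curated
metabolic database, so every feature can participate whether or not it maps
to a known metabolite.

**Transformation edges.** For each unordered pair of peaks and each listed
transformation, an edge is created when |(m_hi − m_lo) − Δ| falls within the
tolerance. The ppm reference mass is the heavier peak, because mass error on
modern instruments scales with measured mass. Edges are oriented low → high
mass, so a neutral loss in fragmentation data is read against the arrow. A
pair matching several transformations yields parallel labelled edges:
ambiguity is information for the annotator, and collapsing to a "best" label
would hide it. Acceptance is inclusive (≤) at the window boundary.

**Adduct edges.** Pairwise adduct inference without an anchor is
underdetermined, so the search presupposes a base ion: each peak in turn is
treated as the base (identity for neutral-mass tables, [M+H]+ or [M−H]− for
positive/negative m/z tables), its neutral mass is inverted through the base
spec, the m/z of every other adduct hypothesis is predicted, and peaks
within tolerance of a prediction — and, optionally, within a retention-time
window of the base, 10 s being the conventional co-elution window — are
linked to the base. The ppm reference is the predicted mass. The base spec
itself is never emitted as an edge label.

**Electron correction.** Offsets are electron-corrected per charge:
[M+H]+ adds the proton mass 1.007276 Da, not the hydrogen atom's
1.007825 Da. At 5 ppm on a 110 Da ion the 0.55 mDa electron mass is exactly
the kind of error that flips a match, so this is not pedantry.

## Search algorithm

Masses are sorted once; for each transformation (or adduct prediction) the
candidate partners are located with binary search inside a conservative
window, then checked exactly. Total work is O(n log n + T·n + matches); the
n² pair matrix is never materialised. A deliberately dumb double-loop
implementation lives in the test suite as the oracle; the sweep must equal
it exactly on randomized instances whose masses are seeded near the
tolerance boundary (±8 ppm around true deltas at a 5 ppm tolerance) so the
boundary itself is exercised.

## Default chemistry tables

The shipped transformation list (`data/transformations.tsv`) and adduct
table (`data/adducts.tsv`) are **reconstructions**: a standard working set
assembled from commonly encountered LC-MS chemistry, with every delta and
offset computed from the embedded atomic monoisotopic mass table (H, C, N,
O, Na, P, S, Cl, K at ≥ 10 significant digits; electron 0.00054858 Da).
Four entries required a formula decision, documented here as this package's
choice:

| name | formula | rationale |
|---|---|---|
| methionine | C5H9NOS | amino-acid residue mass (transfer loses water) |
| diphosphate | H2P2O6 | pyrophosphoryl group, two condensed HPO3 units |
| glucose-N-phosphate | C6H11O8P | glucosyl-phosphate moiety (glycosidic attachment loses water) |
| glyoxalate | C2H2O3 | glyoxylate added by condensation |

Deltas are stored as numbers; formulas are documentation. Matching needs
only the delta, and user tables may omit formulas entirely.

The default adduct table covers [M+H]+, [M+Na]+, [M+K]+, [M+NH4]+,
[M+ACN+H]+, [2M+H]+, [2M+Na]+, [3M+H]+, [M+2H]2+, [M−H]−, [M+Cl]−,
[M+HCOO]−, [2M−H]− — dimers, trimers, a doubly charged species, and the
formate/ammonium adducts that dominate buffer-dependent adduct patterns.
Arbitrary n and z are accepted from user tables.

## Sample match tables and group comparison

An edge is *evidenced* in sample s only when **both** endpoints have an
abundance recorded for s at or above the threshold; a link is only evidence
when both partners are seen, and an absent (unmeasured) cell never passes —
absence is not zero. Thresholds can be raw counts (e.g. 100 000) or log10
intensity (e.g. 6). Count mode tallies evidenced edges per label; ratio mode
averages heavier/lighter abundance ratios over evidenced transform edges
(invertible by flag for loss-dominated fragmentation data), recording the
number of contributing edges and leaving the cell absent when none qualify.

Group contrasts use Welch's unequal-variance t-test per label on the
per-sample cells, two-sided. Welch is the defensible default when nothing
guarantees equal variances across conditions. No multiple-testing
correction is applied by default — the table is a screening device and raw
p-values are reported as such — with Benjamini–Hochberg available by flag.
Rows with fewer than two usable cells in either group are reported
untested, not imputed. When all pooled values are identical the test is
degenerate and p = 1 is reported directly.

## Visual mapping

Node colour interpolates #0000FF → #FF0000 linearly in the mapped quantity
(mass, retention time, or abundance in a chosen sample) and node size
interpolates [min_size, max_size] on the same normalisation; a degenerate
range maps every node to the midpoint (t = 0.5, #800080). Linear rather
than quantile scaling is the simplest faithful reading of "small/blue is
low, large/red is high"; the gradient midpoint naturally passes through
purple. Absent intensities map to 0 — bluest and smallest — which visually
flags features undetected in the selected sample. Edges are coloured by
transformation type class through a user palette, defaulting to grey
(#999999).

## Synthetic data generator

The generator emulates what the matcher consumes: compound masses uniform
in a configurable range (default 150–900 Da), transformation chains of 1–4
steps over five common changes (CH2, C2H2, H2O, CO, NH3), optional adduct
satellites placed by the forward adduct model and co-eluting with their
base, Gaussian ppm mass noise (default 1 ppm, a well-calibrated Orbitrap),
log-normal intensities (log10 mean 6, sd 0.5 — the 10^5–10^7 count regime
where intensity thresholds are meaningful) with 10% multiplicative
between-sample noise, and two groups of four samples.

Two construction rules give the recovery tests sharp meaning:

- **Global exclusion, not just decoys.** Decoys are rejection-sampled
  outside a ppm exclusion window (default 15 ppm, ≥ 3× the tested
  tolerance) of every valid transformation/adduct relation to every
  existing peak — and the same check is applied to the planted chains and
  satellites themselves, resampling any chain whose *unplanned* pairwise
  differences collide with a listed delta. The recorded truth is therefore
  the complete set of valid relations at the tested tolerance, so
  "precision = 1.0" is a well-defined claim rather than an accident of
  what was counted.
- **Group effects on the transformed partner.** A planted ratio effect
  multiplies the abundance of the heavier partner of one label's edges in
  one group's samples, so `ratio_table` sees the effect directly. A peak
  that is the heavier partner of one edge and the lighter of a consecutive
  same-label edge dilutes the effect in that second edge — real chains do
  the same, and the power analysis absorbs it.

The generator does **not** simulate chromatographic peak shapes, isotope
envelopes, correlated intensities, or mass-dependent noise; passing
recovery tests on this data demonstrates correctness of the matching and
counting logic under the stated noise model, not performance on any real
instrument's quirks.

A deterministic `grid_fixture()` builds the 4×3 grid generated by +C2H2
steps across and +O steps down from 200 Da (12 nodes, 17 edges) — the
pattern chain-extension × hydroxylation families form in lipid data.

## Numerical and design choices

- Masses are stored and serialised at full precision (`repr`); nothing is
  rounded on read or write. GraphML and TSV round trips are bit-exact
  (pandas readers need `float_precision="round_trip"` to verify this).
- Tolerance is ppm or mDa; nothing defaults silently in the CLI — exactly
  one tolerance flag is required because it is the single most
  result-determining parameter. The library default is 5 ppm.
- Edge identity is (source, label, target); the GraphML edge id
  `source|label|target` makes outputs diff-stable across runs.
- RT units are taken as given and documented as seconds; no conversion.
- All randomness flows from one integer seed through
  `numpy.random.Generator`; identical configs are bit-reproducible.
- CLI outputs are written atomically (temp file + rename) and every run
  logs its flags, package version and input checksums.

## Problem sizes used in the checks

The bundled verification uses 100-peak instances (25 seeds) for oracle
equivalence, a 200-compound / 100-decoy table (~1100 peaks) for
recall/precision, and 200 simulated two-group experiments each for null
calibration and power at 30 compounds and 8 samples — sizes chosen to
estimate the rates tightly while keeping the whole suite interactive.

## Known limitations

- Adduct inference requires a base ion present at some intensity; pure
  pairwise adduct grouping without an anchor is out of scope.
- Near-isobars are kept, not merged; a peak may legitimately carry
  contradictory labels.
- The per-sample count is per-edge, not per-unique-peak; a hub peak
  contributes once per incident edge.
- No isotopologue handling: a 13C satellite within tolerance of a listed
  delta will be linked like any other peak.
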