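# massdiffnet

Ab-initio mass-difference networks from high-resolution MS peak lists.

Untargeted metabolomics produces long lists of accurate masses, most of
which never map onto a curated metabolic network — yet the features are not
independent: pairs related by a biochemical reaction differ by that
reaction's monoisotopic mass change, and adducts, dimers/trimers and
multi-charge species of one molecule satisfy m/z = (n·M + offset)/z.
`massdiffnet` builds networks directly from these relations: nodes are
measured masses, edges are matched chemical transformations (within a ppm
or mDa tolerance, optionally restricted to co-eluting features) or matched
adduct predictions around a base ion. It then profiles the detected
transformation/adduct types per sample — counts above an intensity
threshold, or mean transformed/untransformed abundance ratios — and tests
two-condition contrasts per label with Welch's t-test. Networks export to
Cytoscape-loadable GraphML/SIF with visual-mapping attributes (blue→red
colour and size gradients over mass, retention time or intensity).

It is written for mass-spectrometrists annotating LC-MS features —
fragmentation graphs, adduct patterns, buffer-dependent adduct formation,
bulk shifts in transformation chemistry between conditions — starting from
a finished peak table (TSV/CSV; no raw-file handling or peak picking).

## Worked example

A selected-fragmentation spectrum reduced to three masses — a precursor at
180.0900 and two fragments:

```
$ printf 'mass\n84.0443\n98.0599\n180.0900\n' > frag.tsv
$ massdiffnet transform-net --peaks frag.tsv --tol-ppm 5 \
      --out-graphml frag.graphml --out-sif frag.sif
3 nodes, 1 edges
$ cat frag.sif
84.0443	CH2	98.0599
180.0900
```

At 5 ppm, exactly one of the three possible pairs matches a transformation
in the built-in list: 98.0599 − 84.0443 = 14.0156 is a CH2 step (expected
14.015650, error ≈ 0.5 ppm of the heavier fragment). The precursor links to
neither fragment, so it appears as an orphan line in the SIF output. The
GraphML file carries mass, error and colour/size attributes and opens
directly in Cytoscape.

The same pipeline at scale, on simulated data with known ground truth:

```
$ massdiffnet simulate --seed 1 --out demo
188 peaks, 128 transform + 0 adduct truth edges
$ massdiffnet sample-table --peaks demo.peaks.tsv --id-column id \
      --rt-column rt --tol-ppm 5 --mode ratio --threshold 1 --out demo.ratios.tsv
7 labels x 8 samples
$ massdiffnet compare --table demo.ratios.tsv \
      --group1 A_1,A_2,A_3,A_4 --group2 B_1,B_2,B_3,B_4 --out demo.compare.tsv
7 labels tested, 0 with p < 0.01
```

`demo.ratios.tsv` holds, per transformation label and sample, the mean
abundance ratio of the heavier (transformed) to the lighter (untransformed)
partner over edges whose endpoints both pass the threshold; the comparison
table reports per-label Welch statistics, e.g.

```
label   mean_group1  mean_group2  statistic  df    p_value  direction  tested
CH2     2.9827       3.0305        0.4637    4.70  0.6636   increase   True
H2O     2.6951       2.8863        0.9188    5.22  0.3987   increase   True
...
```

No label reaches p < 0.01 here because this run plants no group effect —
the two groups differ only by sampling noise. Library use mirrors the CLI:

```python
from massdiffnet import (Tolerance, default_transformations,
                         find_transformation_edges, read_peak_table)

table = read_peak_table("frag.tsv")
edges = find_transformation_edges(table, default_transformations(),
                                  Tolerance("ppm", 5.0))
# [MatchEdge(source_id='84.0443', target_id='98.0599', kind='transform',
#            label='CH2', ...)]
```

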