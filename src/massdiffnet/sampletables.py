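"""Per-sample transformation/adduct profiling and two-group comparison.

The sample match table asks, for every transformation or adduct label and
every sample: how many matched edges are *evidenced* in that sample — both
endpoint peaks present and at or above an intensity threshold — or, in ratio
mode, what is the mean abundance ratio of the heavier (transformed) to the
lighter (untransformed) partner over the evidenced edges.  Group contrasts
(e.g. aerobic vs anaerobic cultures) are tested per label with Welch's
unequal-variance t-test on the per-sample cells, two-sided, with an optional
Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .netbuild import MassDiffNetwork, MatchEdge
from .peakio import PeakTable


@dataclass
class SampleMatchTable:
    """Label x sample matrix of counts or mean ratios.

    ``values`` holds the cells (NaN marks an absent ratio cell: no edge
    qualified); ``n_edges`` the number of edges contributing to each cell.
    """

    values: pd.DataFrame
    n_edges: pd.DataFrame
    mode: str  # "count" | "ratio"
    threshold: float
    threshold_scale: str  # "raw" | "log10"

    @property
    def row_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_labels(self) -> list[str]:
        return list(self.values.columns)


def _passes(abundance: float | None, threshold: float, scale: str) -> bool:
    """Threshold test on the chosen scale; absent or non-positive values
    never pass on the log scale."""
    if abundance is None:
        return False
    if scale == "raw":
        return abundance >= threshold
    if abundance <= 0:
        return False
    return math.log10(abundance) >= threshold


def _check_scale(table: PeakTable, scale: str) -> None:
    if scale not in ("raw", "log10"):
        raise ConfigurationError(f"threshold scale must be 'raw' or 'log10', got {scale!r}")
    if scale == "log10":
        for p in table.peaks:
            for s, a in p.abundances.items():
                if a < 0:
                    raise ValidationError(
                        f"log10 threshold with negative abundance {a} "
                        f"(peak {p.peak_id!r}, sample {s!r})"
                    )


def _label_order(edges: Sequence[MatchEdge]) -> list[str]:
    seen: list[str] = []
    for e in edges:
        if e.label not in seen:
            seen.append(e.label)
    return seen


def count_table(
    net: MassDiffNetwork,
    table: PeakTable,
    threshold: float,
    scale: str = "raw",
) -> SampleMatchTable:
    """Number of edges per label evidenced in each sample.

    An edge counts in sample s only when *both* endpoints have an abundance
    recorded for s at or above the threshold — a link is only evidence when
    both partners are seen.
    """
    if not table.samples:
        raise ConfigurationError("peak table has no sample columns")
    _check_scale(table, scale)
    peaks = table.by_id()
    labels = _label_order(net.edges)
    counts = pd.DataFrame(0, index=labels, columns=table.samples, dtype=int)
    for e in net.edges:
        u, v = peaks[e.source_id], peaks[e.target_id]
        for s in table.samples:
            if _passes(u.abundances.get(s), threshold, scale) and _passes(
                v.abundances.get(s), threshold, scale
            ):
                counts.loc[e.label, s] += 1
    return SampleMatchTable(
        values=counts,
        n_edges=counts.copy(),
        mode="count",
        threshold=threshold,
        threshold_scale=scale,
    )


def ratio_table(
    net: MassDiffNetwork,
    table: PeakTable,
    threshold: float,
    scale: str = "raw",
    invert: bool = False,
) -> SampleMatchTable:
    """Mean transformed/untransformed abundance ratio per label and sample.

    Over transform edges u->v (u lighter = untransformed, v heavier =
    transformed) whose endpoints both pass the threshold in sample s, the
    cell is mean(abundance_s(v) / abundance_s(u)); NaN when no edge
    qualifies.  ``invert`` flips to lighter/heavier for loss-dominated
    (fragmentation) data.  The threshold doubles as the division guard: a
    denominator that passed a positive threshold cannot be zero.
    """
    if not table.samples:
        raise ConfigurationError("peak table has no sample columns")
    if scale == "raw" and threshold <= 0:
        raise ConfigurationError("ratio mode needs a positive raw threshold")
    _check_scale(table, scale)
    peaks = table.by_id()
    tedges = [e for e in net.edges if e.kind == "transform"]
    labels = _label_order(tedges)
    sums = pd.DataFrame(0.0, index=labels, columns=table.samples)
    ns = pd.DataFrame(0, index=labels, columns=table.samples, dtype=int)
    for e in tedges:
        u, v = peaks[e.source_id], peaks[e.target_id]
        for s in table.samples:
            au, av = u.abundances.get(s), v.abundances.get(s)
            if _passes(au, threshold, scale) and _passes(av, threshold, scale):
                r = au / av if invert else av / au
                sums.loc[e.label, s] += r
                ns.loc[e.label, s] += 1
    values = sums / ns.where(ns > 0, other=np.nan)
    return SampleMatchTable(
        values=values,
        n_edges=ns,
        mode="ratio",
        threshold=threshold,
        threshold_scale=scale,
    )


def compare_groups(
    tbl: SampleMatchTable | pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    bh: bool = False,
) -> pd.DataFrame:
    """Welch's two-sample t-test per row label between two sample groups.

    Rows with fewer than two usable (non-absent) cells in either group are
    reported with ``tested=False``.  ``direction`` describes group2 relative
    to group1 (a zero difference reports "increase" with zero means, flagged
    by the equal means themselves).  ``bh=True`` appends Benjamini-Hochberg
    adjusted p-values over the tested rows.
    """
    values = tbl.values if isinstance(tbl, SampleMatchTable) else tbl
    g1, g2 = list(group1), list(group2)
    overlap = set(g1) & set(g2)
    if overlap:
        raise ConfigurationError(f"groups overlap: {sorted(overlap)}")
    for s in g1 + g2:
        if s not in values.columns:
            raise ConfigurationError(f"sample {s!r} not in table columns")

    rows = []
    for label in values.index:
        x = values.loc[label, g1].astype(float).dropna().to_numpy()
        y = values.loc[label, g2].astype(float).dropna().to_numpy()
        rec: dict = {
            "label": label,
            "mean_group1": float(np.mean(x)) if x.size else np.nan,
            "mean_group2": float(np.mean(y)) if y.size else np.nan,
            "statistic": np.nan,
            "df": np.nan,
            "p_value": np.nan,
            "direction": "",
            "tested": False,
        }
        if x.size >= 2 and y.size >= 2:
            pooled = np.concatenate([x, y])
            if np.ptp(pooled) == 0.0:
                # all values identical: no evidence of any difference
                rec.update(statistic=0.0, df=float(x.size + y.size - 2), p_value=1.0)
            else:
                res = stats.ttest_ind(y, x, equal_var=False)
                rec.update(
                    statistic=float(res.statistic),
                    df=float(res.df),
                    p_value=float(res.pvalue),
                )
            rec["tested"] = True
            rec["direction"] = (
                "decrease" if rec["mean_group2"] < rec["mean_group1"] else "increase"
            )
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("label")
    if bh:
        tested = out["tested"]
        p = out.loc[tested, "p_value"].to_numpy()
        out["p_adjusted"] = np.nan
        if p.size:
            out.loc[tested, "p_adjusted"] = stats.false_discovery_control(p, method="bh")
    return out


def write_sample_table(tbl: SampleMatchTable, path: str | Path) -> None:
    """Write cells to ``path`` and contributing edge counts alongside it."""
    path = Path(path)
    tbl.values.to_csv(path, sep="\t", index_label="label")
    n_path = path.with_suffix(path.suffix + ".n_edges.tsv")
    tbl.n_edges.to_csv(n_path, sep="\t", index_label="label")


def read_sample_table_values(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="label")


def write_comparison(comparison: pd.DataFrame, path: str | Path) -> None:
    comparison.to_csv(path, sep="\t", index_label="label")
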