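"""Sample match tables (counts, ratios) and two-group comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from massdiffnet.chemlib import Transformation
from massdiffnet.errors import ConfigurationError
from massdiffnet.netbuild import Tolerance, build_network, find_transformation_edges
from massdiffnet.sampletables import (
    SampleMatchTable,
    compare_groups,
    count_table,
    ratio_table,
    read_sample_table_values,
    write_sample_table,
)
from tests.conftest import make_table

CH2 = Transformation("CH2", 14.0156500638)
PPM5 = Tolerance("ppm", 5.0)


def one_edge_table(ab_u, ab_v):
    """Two peaks joined by one CH2 edge, with given per-sample abundances."""
    table = make_table(
        [100.0, 100.0 + CH2.delta_mass], abundances=[ab_u, ab_v]
    )
    edges = find_transformation_edges(table, [CH2], PPM5)
    assert len(edges) == 1
    return table, build_network(table, edges)


def test_zero_edge_network_gives_all_zero_counts():
    table = make_table([100.0, 300.0], abundances=[{"S": 1.0}, {"S": 1.0}])
    net = build_network(table, [])
    tbl = count_table(net, table, threshold=0.5)
    assert tbl.values.shape == (0, 1)
    assert tbl.mode == "count"


def test_count_both_endpoints_must_pass_threshold():
    table, net = one_edge_table(
        {"SampleA": 2e5, "SampleB": 5e4}, {"SampleA": 3e5, "SampleB": 3e5}
    )
    tbl = count_table(net, table, threshold=1e5, scale="raw")
    assert list(tbl.values.loc["CH2"]) == [1, 0]


def test_count_log10_scale():
    table, net = one_edge_table(
        {"SampleA": 2e5, "SampleB": 5e4}, {"SampleA": 3e5, "SampleB": 3e5}
    )
    # log10(3e5) = 5.48 < 6: nothing passes a log-intensity threshold of 6
    tbl = count_table(net, table, threshold=6.0, scale="log10")
    assert list(tbl.values.loc["CH2"]) == [0, 0]
    # at 5 the SampleA pair passes, SampleB's 5e4 (log10 4.7) still fails
    tbl5 = count_table(net, table, threshold=5.0, scale="log10")
    assert list(tbl5.values.loc["CH2"]) == [1, 0]


def test_absent_abundance_never_passes():
    table, net = one_edge_table({"S1": 2e5}, {})
    tbl = count_table(net, table, threshold=0.0, scale="raw")
    assert tbl.values.loc["CH2", "S1"] == 0


def test_log10_with_negative_abundance_rejected():
    table, net = one_edge_table({"S1": -1.0}, {"S1": 2e5})
    with pytest.raises(Exception, match="negative"):
        count_table(net, table, threshold=1.0, scale="log10")


def test_count_monotone_in_threshold():
    rng = np.random.default_rng(0)
    masses = [100.0, 100.0 + CH2.delta_mass, 200.0, 200.0 + CH2.delta_mass]
    abunds = [{f"S{k}": float(rng.uniform(0, 1e6)) for k in range(4)} for _ in masses]
    table = make_table(masses, abundances=abunds)
    net = build_network(table, find_transformation_edges(table, [CH2], PPM5))
    prev = None
    for thr in [0.0, 1e5, 5e5, 1e6]:
        cur = count_table(net, table, threshold=thr).values
        if prev is not None:
            assert (cur <= prev).all().all()
        prev = cur


def test_ratio_single_edge_and_mean():
    table, net = one_edge_table({"SampleA": 1e6}, {"SampleA": 2e6})
    tbl = ratio_table(net, table, threshold=1e5)
    assert tbl.values.loc["CH2", "SampleA"] == pytest.approx(2.0)
    assert tbl.n_edges.loc["CH2", "SampleA"] == 1

    # two edges with ratios 1.0 and 3.0 -> mean 2.0
    masses = [100.0, 100.0 + CH2.delta_mass, 200.0, 200.0 + CH2.delta_mass]
    abunds = [{"SampleA": 1e6}, {"SampleA": 1e6}, {"SampleA": 1e6}, {"SampleA": 3e6}]
    table = make_table(masses, abundances=abunds)
    net = build_network(table, find_transformation_edges(table, [CH2], PPM5))
    tbl = ratio_table(net, table, threshold=1e5)
    assert tbl.values.loc["CH2", "SampleA"] == pytest.approx(2.0)
    assert tbl.n_edges.loc["CH2", "SampleA"] == 2


def test_ratio_absent_cell_when_no_edge_qualifies():
    table, net = one_edge_table(
        {"SampleA": 1e6, "SampleB": 10.0}, {"SampleA": 2e6, "SampleB": 2e6}
    )
    tbl = ratio_table(net, table, threshold=1e5)
    assert np.isnan(tbl.values.loc["CH2", "SampleB"])
    assert tbl.n_edges.loc["CH2", "SampleB"] == 0


def test_ratio_exact_constant_multiple():
    # every heavier partner is exactly c x its lighter partner -> all cells c
    c = 3.5
    rng = np.random.default_rng(1)
    masses, abunds = [], []
    for i in range(5):
        base = 100.0 + 30 * i
        u = {f"S{k}": float(rng.uniform(1e5, 1e6)) for k in range(3)}
        v = {k: c * a for k, a in u.items()}
        masses += [base, base + CH2.delta_mass]
        abunds += [u, v]
    table = make_table(masses, abundances=abunds)
    net = build_network(table, find_transformation_edges(table, [CH2], PPM5))
    tbl = ratio_table(net, table, threshold=1.0)
    assert np.allclose(tbl.values.to_numpy(dtype=float), c)


def test_ratio_invert_flag():
    table, net = one_edge_table({"S": 1e6}, {"S": 2e6})
    tbl = ratio_table(net, table, threshold=1.0, invert=True)
    assert tbl.values.loc["CH2", "S"] == pytest.approx(0.5)


def test_adduct_edges_excluded_from_ratio():
    from massdiffnet.netbuild import MatchEdge

    table = make_table([100.0, 200.0], abundances=[{"S": 1e6}, {"S": 2e6}])
    adduct = MatchEdge("P0", "P1", "adduct", "[M+Na]+", 200.0, 200.0, 0.0)
    net = build_network(table, [adduct])
    tbl = ratio_table(net, table, threshold=1.0)
    assert tbl.values.empty


# ---------- group comparison ----------


def welch_oracle(x, y):
    """Hand-computed Welch statistic/df/p, independent of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (y.mean() - x.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def frame(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(rows).T


def test_identical_groups_give_p_one():
    df = frame({"CH2": {"a1": 1.0, "a2": 2.0, "b1": 1.0, "b2": 2.0}})
    out = compare_groups(df, ["a1", "a2"], ["b1", "b2"])
    assert out.loc["CH2", "p_value"] == pytest.approx(1.0)
    assert out.loc["CH2", "direction"] == "increase"
    assert out.loc["CH2", "mean_group1"] == out.loc["CH2", "mean_group2"]


def test_clear_decrease_detected_and_matches_oracle():
    g1 = [1.0, 1.1, 0.9, 1.0]
    g2 = [0.5, 0.45, 0.55, 0.5]
    cells = {f"a{i}": v for i, v in enumerate(g1)} | {f"b{i}": v for i, v in enumerate(g2)}
    df = frame({"SO3": cells})
    out = compare_groups(df, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)])
    t, dof, p = welch_oracle(g1, g2)
    assert out.loc["SO3", "p_value"] == pytest.approx(p, rel=1e-9)
    assert out.loc["SO3", "statistic"] == pytest.approx(t, rel=1e-9)
    assert out.loc["SO3", "df"] == pytest.approx(dof, rel=1e-9)
    assert p < 0.01
    assert out.loc["SO3", "direction"] == "decrease"


def test_insufficient_cells_marked_untested():
    df = frame({"CH2": {"a1": 1.0, "a2": 1.2, "b1": 0.5, "b2": np.nan}})
    out = compare_groups(df, ["a1", "a2"], ["b1", "b2"])
    assert not out.loc["CH2", "tested"]
    assert np.isnan(out.loc["CH2", "p_value"])


def test_overlapping_groups_rejected():
    df = frame({"CH2": {"a": 1.0, "b": 2.0, "c": 3.0}})
    with pytest.raises(ConfigurationError):
        compare_groups(df, ["a", "b"], ["b", "c"])


def test_bh_adjustment_column():
    rng = np.random.default_rng(2)
    rows = {
        f"T{i}": {f"a{k}": float(rng.normal(1, 0.1)) for k in range(4)}
        | {f"b{k}": float(rng.normal(1, 0.1)) for k in range(4)}
        for i in range(6)
    }
    df = frame(rows)
    out = compare_groups(df, [f"a{k}" for k in range(4)], [f"b{k}" for k in range(4)], bh=True)
    assert "p_adjusted" in out.columns
    assert (out["p_adjusted"].dropna() >= out["p_value"].dropna() - 1e-12).all()


def test_sample_table_tsv_round_trip(tmp_path):
    table, net = one_edge_table({"S1": 1e6, "S2": 2e6}, {"S1": 2e6, "S2": 2e6})
    tbl = ratio_table(net, table, threshold=1.0)
    path = tmp_path / "tbl.tsv"
    write_sample_table(tbl, path)
    back = read_sample_table_values(path)
    assert back.loc["CH2", "S1"] == pytest.approx(2.0)
    assert (tmp_path / "tbl.tsv.n_edges.tsv").exists()
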