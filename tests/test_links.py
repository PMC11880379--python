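"""Cell aggregates, peak-to-gene links, hkmeans, overlaps, conservation."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from skelconv import links, pseudobulk


def test_aggregate_shapes_and_determinism():
    m1 = links.aggregate_cells(1000, n_aggregates=500, cells_per=100, seed=3)
    assert m1.shape == (500, 100)
    m2 = links.aggregate_cells(1000, n_aggregates=500, cells_per=100, seed=3)
    np.testing.assert_array_equal(m1, m2)
    # population equal to aggregate size: every aggregate is the whole population
    m3 = links.aggregate_cells(100, n_aggregates=5, cells_per=100, seed=0)
    for row in m3:
        assert set(row) == set(range(100))


def test_aggregate_knn_mode_takes_neighbors(rng):
    emb = np.sort(rng.normal(size=50))[:, None]
    m = links.aggregate_cells(50, n_aggregates=10, cells_per=5, seed=1,
                              mode="knn", embedding=emb)
    for row in m:
        vals = np.sort(emb[row].ravel())
        # members are contiguous in the 1-D embedding
        lo, hi = vals[0], vals[-1]
        inside = ((emb.ravel() >= lo) & (emb.ravel() <= hi)).sum()
        assert inside == 5
    with pytest.raises(ValueError):
        links.aggregate_cells(4, n_aggregates=2, cells_per=5, mode="knn", embedding=emb[:4])


def _link_setup(small_cohort, lin, seed=0, n_agg=300, per=80):
    co = small_cohort
    danorm = pseudobulk.normalize_log(co.atac.X)
    rnanorm = pseudobulk.normalize_log(co.rna.X)
    m = np.flatnonzero((co.atac.cells["lineage"] == lin).to_numpy())
    emb = co.atac.cells["pseudotime"].to_numpy()[m][:, None]
    mem = links.aggregate_cells(len(m), n_agg, per, seed=seed, mode="knn", embedding=emb)
    aagg = links.aggregate_means(danorm[:, m], mem)
    rna_pos = {c: i for i, c in enumerate(co.rna.cells.index)}
    rcols = np.array([rna_pos[co.truth.paired_cells[co.atac.cells.index[i]]] for i in m])
    eagg = links.aggregate_means(rnanorm[:, rcols], mem)
    return aagg, eagg, mem


def test_pearson_r_matches_bruteforce(small_cohort):
    co = small_cohort
    aagg, eagg, _ = _link_setup(co, "NC")
    t = links.peak_gene_links(aagg, list(co.atac.feature_ids), co.peaks,
                              eagg, co.rna.feature_ids, co.genes, lineage="NC")
    pi = {p: i for i, p in enumerate(co.atac.feature_ids)}
    gi = {g: i for i, g in enumerate(co.rna.feature_ids)}
    for _, row in t.head(20).iterrows():
        x = aagg[pi[row["peak"]]]
        y = eagg[gi[row["gene"]]]
        r = np.corrcoef(x, y)[0, 1]
        assert row["r"] == pytest.approx(r, abs=1e-10)


def test_window_gate_excludes_distant_pairs(small_cohort):
    co = small_cohort
    aagg, eagg, _ = _link_setup(co, "NC", n_agg=50, per=50)
    t = links.peak_gene_links(aagg, list(co.atac.feature_ids), co.peaks,
                              eagg, co.rna.feature_ids, co.genes,
                              lineage="NC", window=250_000)
    tss = co.genes.set_index("gene_id")["tss"]
    chrom = co.genes.set_index("gene_id")["chrom"]
    pk = co.peaks.set_index("peak_id")
    for _, row in t.iterrows():
        assert pk.loc[row["peak"], "chrom"] == chrom[row["gene"]]
        center = (pk.loc[row["peak"], "start"] + pk.loc[row["peak"], "end"]) // 2
        assert abs(center - tss[row["gene"]]) <= 250_000


def test_link_recovery_and_monotone_thresholds(small_cohort):
    co = small_cohort
    found = {}
    for lin in ("NC", "SOM", "LPM"):
        aagg, eagg, _ = _link_setup(co, lin)
        t = links.peak_gene_links(aagg, list(co.atac.feature_ids), co.peaks,
                                  eagg, co.rna.feature_ids, co.genes, lineage=lin)
        found[lin] = t
    union = set()
    for t in found.values():
        union |= set(map(tuple, t.loc[t["retained"], ["peak", "gene"]].to_numpy()))
    truth = co.truth.planted_links
    assert len(union & truth) / len(truth) > 0.7
    # precision improves with population size (aggregate overlap noise);
    # the full-scale bound is asserted in the acceptance suite
    assert len(union & truth) / len(union) > 0.6
    # retained count shrinks as thresholds tighten
    t = found["NC"]
    n_loose = ((t["r"] >= 0.3) & (t["fdr"] < 1e-2)).sum()
    n_tight = ((t["r"] >= 0.6) & (t["fdr"] < 1e-6)).sum()
    assert n_tight <= n_loose


def test_permuted_aggregates_retain_almost_nothing(small_cohort, rng):
    co = small_cohort
    aagg, eagg, _ = _link_setup(co, "SOM")
    perm = rng.permutation(aagg.shape[1])
    t = links.peak_gene_links(aagg[:, perm], list(co.atac.feature_ids), co.peaks,
                              eagg, co.rna.feature_ids, co.genes, lineage="SOM")
    assert t["retained"].sum() <= max(3, 1e-4 * len(t) + 3)


def test_hkmeans_recovers_planted_blocks(rng):
    a = rng.normal(0, 0.3, size=(20, 6)) + np.array([5, 5, 5, 0, 0, 0])
    b = rng.normal(0, 0.3, size=(20, 6)) + np.array([0, 0, 0, 5, 5, 5])
    M = pd.DataFrame(np.vstack([a, b]))
    labels = links.hkmeans_links(M, k=2)
    assert labels.iloc[:20].nunique() == 1
    assert labels.iloc[20:].nunique() == 1
    assert labels.iloc[0] != labels.iloc[-1]
    # duplicated rows always share a cluster
    M2 = pd.concat([M, M.iloc[[0]]], ignore_index=True)
    l2 = links.hkmeans_links(M2, k=2)
    assert l2.iloc[0] == l2.iloc[-1]


def test_hkmeans_edge_cases(rng):
    M = pd.DataFrame(rng.normal(size=(5, 4)))
    singles = links.hkmeans_links(M, k=5)
    assert singles.nunique() == 5
    with pytest.raises(ValueError):
        links.hkmeans_links(M, k=6)
    with pytest.raises(ValueError):
        links.hkmeans_links(M, k=1)


def _table(pairs, lin):
    return pd.DataFrame({"peak": [p for p, _ in pairs], "gene": [g for _, g in pairs],
                         "lineage": lin, "retained": True})


def test_link_overlap_counts_identical_and_disjoint():
    t = _table([("p1", "g1"), ("p2", "g2")], "a")
    out = links.link_overlap_counts({"a": t, "b": t.assign(lineage="b"),
                                     "c": t.assign(lineage="c")})
    row = out.set_index("group")
    assert row.loc["shared_all", "cres"] == 2 and row.loc["shared_all", "genes"] == 2
    disjoint = links.link_overlap_counts({
        "a": _table([("p1", "g1")], "a"),
        "b": _table([("p2", "g2")], "b"),
        "c": _table([("p3", "g3")], "c"),
    }).set_index("group")
    assert disjoint.loc["shared_all", "cres"] == 0
    assert disjoint.loc["specific_a", "cres"] == 1


def test_shared_genes_exceed_shared_cres_with_lineage_cres():
    """Lineage-specific CREs converging on shared target genes."""
    tables = {}
    for lin in ("a", "b", "c"):
        pairs = [(f"p_{lin}_{i}", f"g{i}") for i in range(10)]
        pairs += [("p_common", "g_common")]
        tables[lin] = _table(pairs, lin)
    out = links.link_overlap_counts(tables).set_index("group")
    assert out.loc["shared_all", "genes"] > out.loc["shared_all", "cres"]
    assert out.loc["shared_all", "genes"] == 11
    assert out.loc["shared_all", "cres"] == 1


def test_mean_conservation_hand_track():
    track = pd.DataFrame({"chrom": "c1", "start": np.arange(10),
                          "end": np.arange(10) + 1,
                          "score": np.arange(10) / 10.0})
    iv = pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 4], "end": [4, 10]},
                      index=["a", "b"])
    means, _ = links.mean_conservation(track, iv)
    assert means["a"] == pytest.approx(np.mean([0, 0.1, 0.2, 0.3]))
    assert means["b"] == pytest.approx(np.mean(np.arange(4, 10) / 10.0))
    # constant track -> the constant
    track2 = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100], "score": [0.42]})
    means2, _ = links.mean_conservation(track2, iv)
    assert np.allclose(means2, 0.42)
    with pytest.raises(ValueError):
        links.mean_conservation(track, pd.DataFrame({"chrom": ["c1"], "start": [5], "end": [5]}))


def test_uncovered_bases_score_zero_and_flagged():
    track = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [5], "score": [1.0]})
    iv = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [10]}, index=["x"])
    means, _ = links.mean_conservation(track, iv)
    assert means["x"] == pytest.approx(0.5)
    assert means.attrs["covered_fraction"]["x"] == pytest.approx(0.5)


def test_planted_conservation_ordering(small_cohort):
    co = small_cohort
    sharing = co.truth.cre_sharing
    ids = sorted(sharing)
    iv = co.peaks.set_index("peak_id").loc[ids, ["chrom", "start", "end"]]
    groups = pd.Series({p: ("common" if sharing[p] == "common" else "specific")
                        for p in ids})
    _, summary = links.mean_conservation(co.conservation, iv, groups)
    s = summary.set_index("group")["mean"]
    assert s["common"] > s["specific"] + 0.2
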