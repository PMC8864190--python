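"""Normal-cell identification, clone clustering, consensus and fishplot export."""

import numpy as np
import pandas as pd
import pytest

from sccnv import (clone_consensus, cluster_clones, export_fishplot_table,
                   identify_normal_cells)
from sccnv.clonal import CloneAssignment
from sccnv.errors import InvalidArgumentError
from sccnv.segment import CNProfile

from test_segmentation import flat_scheme

SCHEME = flat_scheme(200, bin_bp=1_000_000, n_chroms=2)


def cn_profile(cell_id, cn):
    return CNProfile(cell_id=cell_id, cn_per_bin=np.asarray(cn), scheme=SCHEME)


def diploid_cn(cell_id):
    return cn_profile(cell_id, [2] * 200)


def gained_cn(cell_id, start=10, end=40, cn=3):
    v = np.full(200, 2)
    v[start:end] = cn
    return cn_profile(cell_id, v)


class TestIdentifyNormalCells:
    def test_diploid_is_normal(self):
        out = identify_normal_cells({"n1": diploid_cn("n1")})
        assert out == {"n1": True}

    def test_large_event_is_tumor(self):
        out = identify_normal_cells({"t1": gained_cn("t1")})
        assert out == {"t1": False}

    def test_small_event_below_thresholds_stays_normal(self):
        # a 2-bin (2 Mb) blip under min_call_size and under 2% of bins
        prof = gained_cn("c", start=10, end=12)
        out = identify_normal_cells({"c": prof}, min_call_size=3_000_000,
                                    max_abnormal_fraction=0.02)
        assert out["c"] is True

    def test_abnormal_fraction_rule(self):
        # many scattered single-bin events: no big call but 5% abnormal bins
        v = np.full(200, 2)
        v[::20] = 3
        out = identify_normal_cells({"c": cn_profile("c", v)})
        assert out["c"] is False


def ratio_matrix(rows: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(rows).T


class TestClusterClones:
    def test_identical_pair_coclusters(self):
        rng = np.random.default_rng(0)
        base = 1 + 0.0 * rng.standard_normal(50)
        far = np.full(50, 3.0)
        mat = ratio_matrix({"a": base, "b": base.copy(), "c": far})
        asg = cluster_clones(mat, k=2)
        assert asg.labels["a"] == asg.labels["b"] != asg.labels["c"]

    def test_k1_single_cluster(self):
        mat = ratio_matrix({"a": np.ones(10), "b": np.zeros(10)})
        asg = cluster_clones(mat, k=1)
        assert set(asg.labels.values()) == {"C1"}

    def test_k_exceeding_cells_rejected(self):
        mat = ratio_matrix({"a": np.ones(10)})
        with pytest.raises(InvalidArgumentError):
            cluster_clones(mat, k=2)

    def test_labels_ordered_by_cluster_size(self):
        rng = np.random.default_rng(1)
        rows = {f"big{i}": 1 + 0.01 * rng.standard_normal(20) for i in range(6)}
        rows.update({f"small{i}": 4 + 0.01 * rng.standard_normal(20)
                     for i in range(2)})
        asg = cluster_clones(ratio_matrix(rows), k=2)
        assert asg.labels["big0"] == "C1"
        assert asg.labels["small0"] == "C2"

    def test_invariant_to_cell_order(self):
        rng = np.random.default_rng(2)
        rows = {f"c{i}": (i % 3) + 0.05 * rng.standard_normal(30)
                for i in range(12)}
        mat = ratio_matrix(rows)
        asg1 = cluster_clones(mat, k=3)
        asg2 = cluster_clones(mat.iloc[::-1], k=3)
        # same partition: co-membership must agree for every pair
        cells = list(rows)
        for a in cells:
            for b in cells:
                assert (asg1.labels[a] == asg1.labels[b]) == \
                       (asg2.labels[a] == asg2.labels[b])

    def test_restrict_bins_changes_feature_space(self):
        rng = np.random.default_rng(3)
        # groups differ ONLY in the last 10 bins
        rows = {}
        for i in range(4):
            v = np.ones(30) + 0.01 * rng.standard_normal(30)
            rows[f"x{i}"] = v
        for i in range(4):
            v = np.ones(30) + 0.01 * rng.standard_normal(30)
            v[20:] = 2.0
            rows[f"y{i}"] = v
        mat = ratio_matrix(rows)
        mask = np.zeros(30, dtype=bool)
        mask[20:] = True
        asg = cluster_clones(mat, k=2, restrict_bins=mask)
        assert len({asg.labels[f"x{i}"] for i in range(4)}) == 1
        assert len({asg.labels[f"y{i}"] for i in range(4)}) == 1
        assert asg.labels["x0"] != asg.labels["y0"]


def test_suggest_k_recovers_two_groups():
    from sccnv.clonal import suggest_k
    rng = np.random.default_rng(5)
    rows = {f"a{i}": 1 + 0.02 * rng.standard_normal(25) for i in range(6)}
    rows.update({f"b{i}": 2 + 0.02 * rng.standard_normal(25)
                 for i in range(6)})
    assert suggest_k(ratio_matrix(rows), k_range=range(2, 5)) == 2


def make_assignment(labels, samples=None):
    return CloneAssignment(labels=labels,
                           sample_labels=samples or
                           {c: "primary" for c in labels},
                           linkage_tree=np.empty((0, 4)),
                           k=len(set(labels.values())))


class TestCloneConsensus:
    def test_single_clone_consensus_equals_member(self):
        profs = {f"c{i}": gained_cn(f"c{i}") for i in range(5)}
        asg = make_assignment({c: "C1" for c in profs})
        summary = clone_consensus(profs, asg)
        np.testing.assert_array_equal(
            summary.consensus_cn.loc["C1"].to_numpy(),
            profs["c0"].cn_per_bin)

    def test_median_tie_resolves_toward_diploid(self):
        profs = {"a": diploid_cn("a"), "b": gained_cn("b")}
        asg = make_assignment({"a": "C1", "b": "C1"})
        summary = clone_consensus(profs, asg)
        # bins where the two disagree have median 2.5 -> resolved to 2
        assert (summary.consensus_cn.loc["C1"].to_numpy() == 2).all()

    def test_descendant_superset_flagged(self):
        parent_cells = {f"p{i}": gained_cn(f"p{i}") for i in range(4)}
        child_cells = {}
        for i in range(4):
            v = np.full(200, 2)
            v[10:40] = 3    # inherits the parent event
            v[150:190] = 1  # plus its own loss
            child_cells[f"d{i}"] = cn_profile(f"d{i}", v)
        profs = {**parent_cells, **child_cells}
        labels = {c: "C1" for c in parent_cells}
        labels.update({c: "C2" for c in child_cells})
        summary = clone_consensus(profs, make_assignment(labels))
        assert summary.parent_hints["C2"] == "C1"
        assert summary.parent_hints["C1"] is None

    def test_fractions_conserve_cell_counts(self):
        profs = {f"c{i}": gained_cn(f"c{i}") for i in range(6)}
        labels = {f"c{i}": ("C1" if i < 4 else "C2") for i in range(6)}
        samples = {f"c{i}": ("primary" if i % 2 else "relapse")
                   for i in range(6)}
        summary = clone_consensus(profs, make_assignment(labels, samples))
        assert summary.counts.to_numpy().sum() == 6
        np.testing.assert_allclose(summary.fractions.sum(axis=1), 1.0)


class TestFishplotExport:
    def _summary(self):
        profs = {"a": gained_cn("a"), "b": gained_cn("b")}
        return clone_consensus(profs, make_assignment(
            {"a": "C1", "b": "C1"}, {"a": "primary", "b": "primary"}))

    def test_single_sample_single_clone(self):
        table = export_fishplot_table(self._summary(), ["primary"])
        assert len(table) == 1
        assert table.iloc[0]["fraction"] == 1.0

    def test_fractions_sum_to_one_per_sample(self):
        profs = {f"c{i}": gained_cn(f"c{i}") for i in range(6)}
        labels = {f"c{i}": ("C1" if i < 4 else "C2") for i in range(6)}
        samples = {f"c{i}": ("primary" if i < 3 else "relapse")
                   for i in range(6)}
        summary = clone_consensus(profs, make_assignment(labels, samples))
        table = export_fishplot_table(summary, ["primary", "relapse"])
        sums = table.groupby("sample")["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_unknown_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            export_fishplot_table(self._summary(), ["nonexistent"])
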