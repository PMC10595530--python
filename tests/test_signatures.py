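"""Signature scoring, expressing fractions and group statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as st

from ewstme.containers import CountMatrix, NormMatrix
from ewstme.signatures import (
    COSTIM_GENES,
    DYSFUNCTION_PANEL,
    SignatureSet,
    compare_groups,
    default_signatures,
    dunn_test,
    dysfunction_score,
    expressing_fraction,
    module_score,
    read_gmt,
    write_gmt,
    zscore_signature,
)
from ewstme.synthetic import SimConfig, simulate_cohort
from ewstme.preprocess import normalize


def _nm(arr, genes=None, cells=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{i}" for i in range(arr.shape[1])]
    return NormMatrix(arr, genes, cells)


class TestGMT:
    def test_round_trip(self, tmp_path):
        sets = {
            "a": SignatureSet("a", ("x", "y"), "first"),
            "b": SignatureSet("b", ("z",), "second"),
        }
        write_gmt(sets, tmp_path / "s.gmt")
        back = read_gmt(tmp_path / "s.gmt")
        assert back["a"].genes == ("x", "y") and back["b"].description == "second"

    def test_packaged_signatures_include_hla_and_dysfunction_panels(self):
        sigs = default_signatures()
        assert set(sigs["hla_class_i"].genes) == {"HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "B2M"}
        assert set(DYSFUNCTION_PANEL) <= set(sigs["dysfunction"].genes)
        assert set(COSTIM_GENES) == set(sigs["costimulatory"].genes)

    def test_empty_and_duplicated_sets_rejected(self):
        with pytest.raises(ValueError):
            SignatureSet("bad", ())
        with pytest.raises(ValueError):
            SignatureSet("bad", ("a", "a"))


class TestModuleScore:
    def test_uniform_matrix_scores_zero(self):
        nm = _nm(np.full((6, 4), 2.5))
        s = module_score(nm, SignatureSet("s", ("g0", "g2")), n_bins=2, n_ctrl=2, seed=0)
        assert np.allclose(s, 0.0)

    def test_single_bin_full_control_equals_mean_minus_grand_mean(self, rng):
        X = rng.lognormal(size=(6, 3))
        nm = _nm(X)
        s = module_score(nm, SignatureSet("s", ("g1", "g4")), n_bins=1, n_ctrl="all", seed=3)
        expected = X[[1, 4]].mean(axis=0) - X.mean(axis=0)
        assert np.allclose(s.to_numpy(), expected, atol=1e-12)

    def test_deterministic_and_missing_genes_dropped(self, norm):
        sig = SignatureSet("s", ("HLA-A", "HLA-B", "NOT_A_GENE"))
        with pytest.warns(UserWarning, match="absent"):
            a = module_score(norm, sig, seed=4)
        with pytest.warns(UserWarning):
            b = module_score(norm, sig, seed=4)
        assert np.allclose(a, b)

    def test_fully_absent_signature_rejected(self, norm):
        with pytest.raises(ValueError, match="no gene"):
            module_score(norm, SignatureSet("s", ("NOPE1", "NOPE2")))

    def test_random_sets_score_zero_on_average(self, norm, rng):
        # the binned-control construction is unbiased: random signatures
        # should center on zero
        means = []
        for k in range(100):
            genes = rng.choice(norm.genes.to_numpy(), size=15, replace=False)
            s = module_score(norm, SignatureSet(f"r{k}", tuple(genes)), seed=k)
            means.append(float(s.mean()))
        assert abs(np.mean(means)) <= 0.02


class TestZscoreSignature:
    def test_singleton_equals_gene_zscore(self, rng):
        X = rng.normal(size=(3, 10))
        nm = _nm(X)
        s = zscore_signature(nm, SignatureSet("s", ("g1",)))
        expected = (X[1] - X[1].mean()) / X[1].std()
        assert np.allclose(s, expected)

    def test_cell_at_dataset_mean_scores_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [4.0, 6.0, 8.0]])  # middle cell at both means
        nm = _nm(X)
        s = zscore_signature(nm, SignatureSet("s", ("g0", "g1")))
        assert s.iloc[1] == pytest.approx(0.0)

    def test_hand_computed_two_gene_mean(self):
        X = np.array([[0.0, 2.0, 4.0, 6.0], [1.0, 1.0, 3.0, 3.0]])
        nm = _nm(X)
        s = zscore_signature(nm, SignatureSet("s", ("g0", "g1")))
        z0 = (X[0] - 3.0) / X[0].std()
        z1 = (X[1] - 2.0) / X[1].std()
        assert np.allclose(s, (z0 + z1) / 2)

    def test_zero_variance_gene_defined_zero_with_warning(self):
        X = np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        nm = _nm(X)
        with pytest.warns(UserWarning, match="zero-variance"):
            s = zscore_signature(nm, SignatureSet("s", ("g0", "g1")))
        assert np.isfinite(s).all()


class TestDysfunctionScore:
    def test_monotone_in_panel_expression(self):
        # half the cells silent on every panel gene, half strongly positive
        panel = list(DYSFUNCTION_PANEL)
        other = [f"x{i}" for i in range(40)]
        rng = np.random.default_rng(1)
        X = rng.lognormal(size=(len(panel) + 40, 20))
        X[: len(panel), :10] = 0.0
        X[: len(panel), 10:] = 8.0
        nm = _nm(X, genes=panel + other)
        s = dysfunction_score(nm, seed=0)
        assert s.iloc[:10].max() <= s.iloc[10:].min()

    def test_high_panel_cd8_subset_scores_highest(self):
        markers = dict(
            CD8_T=("CD8A", "GZMA"), CD8_dys=("CD8A", "GZMA"), NK=("GNLY", "PRF1")
        )
        cfg = SimConfig(
            seed=6, n_samples=4, n_patients=2, cells_per_sample=(120, 120), n_genes=400,
            cell_type_proportions={"CD8_T": 0.4, "CD8_dys": 0.3, "NK": 0.3},
            marker_programs=markers, cnv_events=[], genes_per_cnv_arm=0,
            costim_expression_probs={}, lr_axes=[], cd8_type="CD8_T",
        )
        # plant the inhibitory-receptor program directly as CD8_dys markers
        cfg.marker_programs["CD8_dys"] = tuple(["CD8A", "GZMA", *DYSFUNCTION_PANEL])
        counts, cells, _, _ = simulate_cohort(cfg)
        s = dysfunction_score(normalize(counts), seed=0)
        means = s.groupby(cells["cell_type"]).mean()
        assert means.idxmax() == "CD8_dys"

    def test_absent_panel_rejected(self, rng):
        nm = _nm(rng.normal(size=(4, 5)))
        with pytest.raises(ValueError):
            dysfunction_score(nm, SignatureSet("p", ("LAG3", "TIGIT")))


class TestExpressingFraction:
    def _cohort(self):
        arr = np.zeros((3, 14), dtype=int)
        arr[0, :3] = 1        # CD83 in 3 of first 10 cells' group
        arr[2, :] = 1         # housekeeping so no zero-depth cells
        genes = ["CD83", "CD86", "HK"]
        cells = [f"c{i}" for i in range(14)]
        cm = CountMatrix(sp.csr_matrix(arr), genes, cells)
        meta = pd.DataFrame(
            {
                "sample_id": ["s1"] * 14,
                "cell_type": ["cDC"] * 10 + ["Mo"] * 4,
            },
            index=pd.Index(cells, name="cell_id"),
        )
        return cm, meta

    def test_fraction_counted_by_hand_and_zero_case(self):
        cm, meta = self._cohort()
        out = expressing_fraction(cm, meta, genes=("CD83", "CD86"), min_cells=5)
        cdc = out[out["group"] == "cDC"].set_index("gene")["fraction"]
        assert cdc["CD83"] == pytest.approx(0.3)
        assert cdc["CD86"] == 0.0

    def test_groups_under_min_cells_omitted(self):
        cm, meta = self._cohort()
        out = expressing_fraction(cm, meta, genes=("CD83",), min_cells=5)
        assert "Mo" not in set(out["group"])  # only 4 Mo cells
        out2 = expressing_fraction(cm, meta, genes=("CD83",), min_cells=4)
        assert "Mo" in set(out2["group"])

    def test_unknown_gene_warns_and_all_small_notice(self):
        cm, meta = self._cohort()
        with pytest.warns(UserWarning, match="unknown"):
            out = expressing_fraction(cm, meta, genes=("CD83", "NOPE"), min_cells=5)
        assert set(out["gene"]) == {"CD83"}
        with pytest.warns(UserWarning, match="< 99"):
            empty = expressing_fraction(cm, meta, genes=("CD83",), min_cells=99)
        assert empty.empty


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        vals = pd.Series([1.0] * 10)
        groups = pd.Series(["a"] * 5 + ["b"] * 5)
        out = compare_groups(vals, groups, test="wilcoxon")
        assert out["p"].iloc[0] == 1.0 and not out["significant"].iloc[0]

    def test_mannwhitney_exact_enumeration(self):
        vals = pd.Series([1, 2, 3, 4, 5, 6], dtype=float)
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        out = compare_groups(vals, groups, test="mannwhitney")
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_p_equal_alpha_flagged_significant(self):
        # the <= rule: a contrast exactly at the threshold counts
        vals = pd.Series([1, 2, 3, 4, 5, 6], dtype=float)
        groups = pd.Series(["a"] * 3 + ["b"] * 3)
        out = compare_groups(vals, groups, test="mannwhitney", alpha=0.1)
        assert out["p"].iloc[0] == pytest.approx(0.1) and bool(out["significant"].iloc[0])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))

    def test_kruskal_dunn_three_groups(self, rng):
        vals = pd.Series(np.r_[rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        groups = pd.Series(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        out = compare_groups(vals, groups, test="kruskal_dunn")
        out = out.set_index(["group_a", "group_b"])
        assert out.loc[("a", "c"), "significant"]
        assert out.loc[("b", "c"), "significant"]
        assert not out.loc[("a", "b"), "significant"]
        with pytest.raises(ValueError):
            compare_groups(vals, groups.replace("c", "b"), test="kruskal_dunn")

    def test_dunn_z_matches_hand_computation_without_ties(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        groups = pd.Series(["a", "a", "b", "b", "c", "c"])
        out = dunn_test(vals, groups, adjust=None).set_index(["group_a", "group_b"])
        # mean ranks 1.5, 3.5, 5.5; var_base = N(N+1)/12 = 3.5
        se = np.sqrt(3.5 * (0.5 + 0.5))
        assert out.loc[("a", "c"), "z"] == pytest.approx((1.5 - 5.5) / se)
        assert out.loc[("a", "b"), "z"] == pytest.approx((1.5 - 3.5) / se)
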