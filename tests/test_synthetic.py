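"""Generator correctness: planted structure is recovered from raw counts."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from ewstme.signatures import COSTIM_GENES, HLA_CLASS_I
from ewstme.synthetic import (
    CNVEvent,
    LRAxis,
    SimConfig,
    SimTruth,
    build_gene_table,
    plant_dysfunction_axis,
    read_cohort,
    simulate_cohort,
    write_cohort,
)


def _null_config(**kw):
    """No markers, no CNV, no HLA effect, no axes: exchangeable cell types."""
    base = dict(
        seed=3,
        n_samples=4,
        n_patients=2,
        cells_per_sample=(150, 150),
        n_genes=500,
        cell_type_proportions={"tumor": 0.5, "CD8_T": 0.5},
        marker_programs={},
        cnv_events=[],
        genes_per_cnv_arm=0,
        hla_downreg_factor=1.0,
        costim_expression_probs={},
        lr_axes=[],
        dysfunction_coupling=0.0,
        panel_cd8_boost=1.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateCohort:
    def test_same_seed_gives_byte_identical_counts(self):
        cfg = _null_config()
        a, _, _, _ = simulate_cohort(cfg)
        b, _, _, _ = simulate_cohort(_null_config())
        assert (a.X != b.X).nnz == 0
        assert a.genes.equals(b.genes) and a.cells.equals(b.cells)

    def test_null_config_means_equal_across_types(self):
        counts, cells, _, _ = simulate_cohort(_null_config())
        X = counts.to_dense()
        tum = (cells["cell_type"] == "tumor").to_numpy()
        mean_a, mean_b = X[:, tum].mean(), X[:, ~tum].mean()
        assert mean_a / mean_b == pytest.approx(1.0, rel=0.03)
        # per-gene, no systematic type effect: rank-sum on per-gene ratios
        ratios = X[:, tum].mean(axis=1) / np.maximum(X[:, ~tum].mean(axis=1), 1e-9)
        assert np.median(ratios) == pytest.approx(1.0, abs=0.08)

    def test_planted_arm_fold_recovered_in_count_ratio(self):
        cfg = _null_config(
            cnv_events=[CNVEvent("8q", 1.5)],
            genes_per_cnv_arm=200,
            cells_per_sample=(250, 250),
            n_genes=1000,
            seed=9,
        )
        counts, cells, genes, _ = simulate_cohort(cfg)
        X = counts.to_dense()
        arm = (genes["arm"] == "8q").to_numpy()
        tum = (cells["cell_type"] == "tumor").to_numpy()
        ratio = X[np.ix_(arm, tum)].mean() / X[np.ix_(arm, ~tum)].mean()
        assert ratio == pytest.approx(1.5, rel=0.05)

    def test_hla_downregulation_factor_recovered(self, cohort):
        counts, cells, genes, truth = cohort
        assert truth.config.hla_downreg_factor == 0.3
        X = counts.to_dense()
        hla = genes.index.isin(HLA_CLASS_I).astype(bool)
        tum = (cells["cell_type"] == "tumor").to_numpy()
        ratio = X[np.ix_(hla, tum)].mean() / X[np.ix_(hla, ~tum)].mean()
        assert ratio == pytest.approx(0.3, rel=0.10)

    def test_library_sizes_follow_configured_lognormal(self):
        cfg = _null_config(seed=21, cells_per_sample=(300, 300))
        counts, _, _, _ = simulate_cohort(cfg)
        depth = counts.depth()
        mu, sigma = cfg.depth_lognormal
        target = cfg.median_depth * np.exp(mu + sigma**2 / 2)
        se = depth.std(ddof=1) / np.sqrt(len(depth))
        assert abs(depth.mean() - target) < 3 * se

    def test_costim_fraction_monotone_in_planted_probability(self):
        fracs = []
        for p in (0.05, 0.2, 0.5):
            cfg = _null_config(
                seed=5,
                cell_type_proportions={"cDC": 1.0},
                costim_expression_probs={("cDC", g): p for g in COSTIM_GENES},
            )
            counts, _, _, _ = simulate_cohort(cfg)
            sub = counts.subset(genes=list(COSTIM_GENES))
            fracs.append((sub.to_dense() > 0).mean())
        assert fracs[0] < fracs[1] < fracs[2]

    def test_truth_records_cnv_state_and_labels(self, cohort):
        _, cells, _, truth = cohort
        assert truth.cells["cell_type"].equals(cells["cell_type"])
        tum = truth.cells["cell_type"] == "tumor"
        assert (truth.cnv_state.loc[tum, "1q"] == 1.5).all()
        assert (truth.cnv_state.loc[~tum, "1q"] == 1.0).all()

    @pytest.mark.parametrize(
        "bad",
        [
            dict(cells_per_sample=(0, 0)),
            dict(cell_type_proportions={}),
            dict(cell_type_proportions={"tumor": 0.7, "CD8_T": 0.7}),
            dict(n_patients=99),
            dict(cnv_events=[CNVEvent("1q", -1.0)]),
            dict(nb_dispersion=0.0),
        ],
    )
    def test_degenerate_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_cohort(_null_config(**bad))


class TestDysfunctionAxis:
    def _truth(self, coupling=0.5, noise=0.0, n_samples=12, seed=2):
        cfg = _null_config(
            seed=seed,
            n_samples=n_samples,
            n_patients=min(8, n_samples),
            cells_per_sample=(20, 25),
            n_genes=120,
            cell_type_proportions={"CD8_T": 0.5, "Mphi": 0.5},
            lr_axes=[LRAxis("NECTIN2", "TIGIT", "Mphi", "CD8_T")],
            dysfunction_coupling=coupling,
            dysfunction_noise_sd=noise,
        )
        _, _, _, truth = simulate_cohort(cfg)
        return truth

    def test_zero_coupling_gives_equal_expected_dysfunction(self):
        truth = plant_dysfunction_axis(self._truth(), coupling=0.0)
        assert truth.expected_dysfunction.nunique() == 1

    def test_positive_coupling_preserves_strength_ranking(self):
        truth = plant_dysfunction_axis(self._truth(), coupling=0.7)
        s = np.log(truth.axis_strengths.iloc[:, 0])
        assert (s.rank() == truth.expected_dysfunction.rank()).all()

    def test_no_axes_or_no_cd8_raises(self):
        truth = self._truth()
        empty = SimTruth(
            truth.cells, truth.cnv_state, truth.axis_strengths.iloc[:, :0],
            truth.expected_dysfunction, truth.config,
        )
        with pytest.raises(ValueError, match="axes"):
            plant_dysfunction_axis(empty, 0.5)
        no_cd8 = SimTruth(
            truth.cells.assign(cell_type="Mphi"), truth.cnv_state,
            truth.axis_strengths, truth.expected_dysfunction, truth.config,
        )
        with pytest.raises(ValueError, match="CD8"):
            plant_dysfunction_axis(no_cd8, 0.5)

    def test_replicate_spearman_matches_designed_population_value(self):
        # coupling 0.5 with noise sd 0.36 targets population Spearman ~0.8;
        # many samples per replicate keep the small-sample bias negligible
        rhos = []
        for seed in range(200):
            truth = self._truth(noise=0.36, n_samples=48, seed=seed)
            rho = st.spearmanr(
                np.log(truth.axis_strengths.iloc[:, 0]), truth.expected_dysfunction
            ).statistic
            rhos.append(rho)
        assert np.mean(rhos) == pytest.approx(0.8, abs=0.05)


class TestCohortIO:
    def test_round_trip_is_lossless(self, cohort, tmp_path):
        counts, cells, genes, truth = cohort
        write_cohort(counts, cells, genes, truth, tmp_path)
        counts2, cells2, genes2, truth2 = read_cohort(tmp_path)
        assert (counts.X != counts2.X).nnz == 0
        assert counts.genes.equals(counts2.genes)
        pd.testing.assert_frame_equal(cells, cells2, check_like=True)
        pd.testing.assert_series_equal(
            truth.expected_dysfunction, truth2.expected_dysfunction
        )
        pd.testing.assert_frame_equal(truth.axis_strengths, truth2.axis_strengths)

    def test_zero_count_gene_preserved(self, tmp_path):
        cfg = _null_config(n_genes=200, cells_per_sample=(30, 30))
        counts, cells, genes, truth = simulate_cohort(cfg)
        counts.X[counts.genes.get_loc("GENE0001"), :] = 0
        counts.X.eliminate_zeros()
        write_cohort(counts, cells, genes, truth, tmp_path)
        counts2, _, _, _ = read_cohort(tmp_path)
        assert counts2.shape == counts.shape
        assert "GENE0001" in counts2.genes

    def test_mtx_header_has_dims_and_nnz(self, tmp_path):
        import scipy.sparse as sp

        from ewstme.containers import CountMatrix

        X = sp.csr_matrix(np.array([[1, 0], [0, 2], [3, 4]]))
        cm = CountMatrix(X, ["a", "b", "c"], ["x", "y"])
        cells = pd.DataFrame(
            {"sample_id": ["s", "s"], "patient_id": ["p", "p"],
             "treatment_status": ["naive", "naive"], "cell_type": ["t", "t"]},
            index=pd.Index(["x", "y"], name="cell_id"),
        )
        genes = pd.DataFrame(
            {"chromosome": ["1"] * 3, "arm": ["1p"] * 3, "start_bp": [1, 2, 3]},
            index=pd.Index(["a", "b", "c"], name="symbol"),
        )
        write_cohort(cm, cells, genes, None, tmp_path)
        lines = [
            l for l in (tmp_path / "matrix.mtx").read_text().splitlines()
            if not l.startswith("%")
        ]
        assert lines[0].split() == ["3", "2", "4"]

    def test_dimension_mismatch_rejected(self, cohort, tmp_path):
        counts, cells, genes, truth = cohort
        with pytest.raises(ValueError, match="rows"):
            write_cohort(counts, cells.iloc[:5], genes, truth, tmp_path)


def test_gene_table_arms_consistent():
    table = build_gene_table(SimConfig())
    assert table.index.is_unique
    assert (table["arm"].str[:-1] == table["chromosome"]).all()
    # orderable within chromosome: q genes after p genes
    for chrom, sub in table.groupby("chromosome"):
        p = sub[sub["arm"].str.endswith("p")]["start_bp"]
        q = sub[sub["arm"].str.endswith("q")]["start_bp"]
        if len(p) and len(q):
            assert p.max() < q.min()
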