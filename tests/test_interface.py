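import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from micronets import (CountMatrix, GroupDesign, WorkflowConfig,
                       generate_synthetic, run_workflow)
from micronets.cli import main as cli_main
from micronets.io import (bundle_from_edge_list, read_association,
                          read_count_table, read_edge_list,
                          write_association, write_count_table,
                          write_edge_list)
from micronets.workflow import construct_network


@pytest.fixture
def dataset():
    return generate_synthetic(p=8, n=24, seed=13)


class TestCountIO:
    def test_tsv_roundtrip(self, dataset, tmp_path):
        path = write_count_table(dataset.counts, tmp_path / "c.tsv")
        back = read_count_table(path)
        np.testing.assert_array_equal(back.values, dataset.counts.values)
        assert back.sample_ids == dataset.counts.sample_ids
        assert back.taxon_ids == dataset.counts.taxon_ids

    def test_orientation_transpose(self, dataset, tmp_path):
        df = dataset.counts.to_frame().T  # taxa x samples on disk
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t")
        back = read_count_table(path, orientation="taxa_by_samples")
        np.testing.assert_array_equal(back.values, dataset.counts.values)

    def test_negative_cell_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\ta\tb\nS1\t3\t-2\n")
        with pytest.raises(ValueError, match="S1"):
            read_count_table(path)

    def test_duplicate_labels_error(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("id\ta\ta\nS1\t1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_count_table(path)

    def test_biom_json_matches_tsv(self, dataset, tmp_path):
        counts = dataset.counts
        tsv = write_count_table(counts, tmp_path / "c.tsv")
        doc = {
            "format": "Biological Observation Matrix 1.0.0",
            "type": "OTU table",
            "matrix_type": "sparse",
            "shape": [counts.n_taxa, counts.n_samples],
            "rows": [{"id": t, "metadata": None}
                     for t in counts.taxon_ids],
            "columns": [{"id": s, "metadata": None}
                        for s in counts.sample_ids],
            "data": [[i, k, counts.values[k, i]]
                     for i in range(counts.n_taxa)
                     for k in range(counts.n_samples)
                     if counts.values[k, i] != 0],
        }
        biom = tmp_path / "c.biom"
        biom.write_text(json.dumps(doc))
        from_tsv = read_count_table(tsv)
        from_biom = read_count_table(biom, format="biom")
        np.testing.assert_array_equal(from_biom.values, from_tsv.values)
        assert from_biom.taxon_ids == from_tsv.taxon_ids

    def test_biom_hdf5_roundtrip(self, dataset, tmp_path):
        import h5py
        from scipy.sparse import csr_matrix

        counts = dataset.counts
        mat = csr_matrix(counts.values.T)  # observations x samples
        path = tmp_path / "c2.biom"
        with h5py.File(path, "w") as f:
            f.create_dataset("observation/ids",
                             data=[t.encode() for t in counts.taxon_ids])
            f.create_dataset("sample/ids",
                             data=[s.encode() for s in counts.sample_ids])
            f.create_dataset("observation/matrix/data", data=mat.data)
            f.create_dataset("observation/matrix/indices", data=mat.indices)
            f.create_dataset("observation/matrix/indptr", data=mat.indptr)
        back = read_count_table(path, format="biom")
        np.testing.assert_array_equal(back.values, counts.values)


class TestAssociationIO:
    def test_roundtrip_bit_exact(self, dataset, tmp_path):
        from micronets import SparccConfig, sparcc
        a = sparcc(dataset.counts, SparccConfig(n_outer=2, seed=0))
        path = write_association(a, tmp_path / "assoc.tsv")
        back = read_association(path, measure="sparcc")
        np.testing.assert_array_equal(back.values, a.values)

    def test_external_matrix_enters_pipeline(self, dataset, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.uniform(-0.8, 0.8, (8, 8))
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 1.0)
        from micronets import AssociationMatrix
        a = AssociationMatrix(vals, list(dataset.counts.taxon_ids),
                              measure="pearson", n_samples=24)
        bundle, _ = construct_network(None, WorkflowConfig(), assoc=a)
        assert bundle.n_edges > 0


class TestEdgeList:
    def test_bit_exact_roundtrip(self, dataset, tmp_path):
        bundle, _ = construct_network(dataset.counts, WorkflowConfig())
        path = write_edge_list(bundle, tmp_path / "edges.tsv")
        df = read_edge_list(path)
        back = bundle_from_edge_list(df, bundle.node_ids)
        np.testing.assert_array_equal(back.similarity, bundle.similarity)
        np.testing.assert_array_equal(
            np.where(bundle.edge_indicator, bundle.dissimilarity, 0.0),
            back.dissimilarity)
        np.testing.assert_array_equal(back.edge_indicator,
                                      bundle.edge_indicator)


class TestConfig:
    def test_yaml_parsing(self, tmp_path):
        doc = {
            "preprocess": {"zero_method": "bayes_mult",
                           "norm_method": "clr",
                           "filter": {"taxa_rule": "top_k_frequency",
                                      "taxa_param": 5}},
            "association": {"measure": "spearman"},
            "sparsify": {"method": "ttest", "alpha": 0.1,
                         "adjust": "BH"},
            "adjacency": {"diss_mode": "unsigned"},
            "compare": {"n_perm": 123, "seed": 9},
        }
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(doc))
        cfg = WorkflowConfig.from_yaml(path)
        assert cfg.zero_method == "bayes_mult"
        assert cfg.measure == "spearman"
        assert cfg.sparsify_method == "ttest"
        assert cfg.alpha == 0.1
        assert cfg.filter.taxa_param == 5
        assert cfg.n_perm == 123
        assert cfg.seed == 9

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="measure"):
            WorkflowConfig(measure="magic")

    def test_non_aware_combination_warns(self):
        with pytest.warns(RuntimeWarning, match="compositionally"):
            WorkflowConfig(measure="pearson", norm_method="TSS")

    def test_aware_combinations_silent(self, recwarn):
        WorkflowConfig(measure="sparcc", norm_method=None)
        WorkflowConfig(measure="pearson", norm_method="clr")
        assert not [w for w in recwarn.list
                    if "compositionally" in str(w.message)]


class TestRunWorkflow:
    def test_construct_artifacts_and_determinism(self, dataset, tmp_path):
        cfg = WorkflowConfig(seed=3)
        out1 = tmp_path / "run1"
        out2 = tmp_path / "run2"
        run_workflow(cfg, dataset.counts, out1, mode="construct")
        run_workflow(cfg, dataset.counts, out2, mode="construct")
        for name in ("edges.tsv", "network.graphml", "analysis.json",
                     "workflow.log"):
            assert (out1 / name).exists()
        assert (out1 / "analysis.json").read_text() == \
            (out2 / "analysis.json").read_text()

    def test_compare_identical_halves_all_zero(self, dataset, tmp_path):
        counts = dataset.counts
        dup = CountMatrix(np.vstack([counts.values, counts.values]),
                          [f"{s}_{g}" for g in (1, 2)
                           for s in counts.sample_ids],
                          list(counts.taxon_ids))
        design = GroupDesign(np.array([0] * 24 + [1] * 24))
        cfg = WorkflowConfig(seed=1, n_perm=30)
        out = tmp_path / "cmp"
        run_workflow(cfg, dup, out, mode="compare", design=design)
        doc = json.loads((out / "comparison.json").read_text())
        for metric in doc["global"].values():
            assert metric["abs_diff"] == pytest.approx(0.0, abs=1e-12)
            assert metric["pvalue"] == pytest.approx(1.0)

    def test_samplenet_mode(self, dataset, tmp_path):
        out = tmp_path / "sn"
        run_workflow(WorkflowConfig(), dataset.counts, out,
                     mode="samplenet")
        assert (out / "sample_edges.tsv").exists()

    def test_diffnet_mode(self, dataset, tmp_path):
        design = GroupDesign(np.array([0] * 12 + [1] * 12))
        out = tmp_path / "dn"
        run_workflow(WorkflowConfig(seed=1), dataset.counts, out,
                     mode="diffnet", design=design)
        doc = json.loads((out / "diffnet.json").read_text())
        assert "n_edges" in doc


class TestCli:
    def test_simulate_then_construct(self, tmp_path):
        runner = CliRunner()
        prefix = tmp_path / "sim"
        res = runner.invoke(cli_main, ["simulate", "--taxa", "8",
                                       "--samples", "20", "--seed", "4",
                                       "--out", str(prefix)])
        assert res.exit_code == 0, res.output
        out = tmp_path / "net"
        res = runner.invoke(cli_main, ["construct",
                                       str(prefix) + ".counts.tsv",
                                       "--seed", "1", "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert (out / "analysis.json").exists()

    def test_config_error_exit_code(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.yaml"
        bad.write_text("association:\n  measure: nonsense\n")
        counts = tmp_path / "c.tsv"
        counts.write_text("id\ta\tb\nS1\t1\t2\nS2\t2\t1\nS3\t1\t1\n")
        res = runner.invoke(cli_main, ["construct", str(counts),
                                       "--config", str(bad),
                                       "--out", str(tmp_path / "o")])
        assert res.exit_code == 2

    def test_data_error_exit_code(self, tmp_path):
        runner = CliRunner()
        counts = tmp_path / "neg.tsv"
        counts.write_text("id\ta\tb\nS1\t1\t-2\n")
        res = runner.invoke(cli_main, ["construct", str(counts),
                                       "--out", str(tmp_path / "o")])
        assert res.exit_code == 3
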