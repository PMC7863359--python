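"""Gene-set parsing, matrix/clinical loading and dataset assembly."""

import numpy as np
import pandas as pd
import pytest

import sigsurvnet as ssn
from sigsurvnet.pathway_data import (AssemblyError, ClinicalFormatError,
                                     MatrixFormatError, PathwayFileError,
                                     parse_stage)


def write(path, text):
    path.write_text(text)
    return path


# ----------------------------------------------------------------- pathways

class TestLoadPathways:
    def test_packaged_fixture_has_46_named_pathways(self):
        pc = ssn.load_pathways(ssn.default_pathway_file())
        assert len(pc) == 46
        for name in ("MAPK", "PI3K-Akt", "Cell cycle"):
            assert name in pc.names

    def test_duplicate_genes_within_pathway_collapse(self, tmp_path):
        f = write(tmp_path / "p.gmt", "P1\tdesc\tA\tB\tA\n")
        pc = ssn.load_pathways(f)
        assert pc.names == ("P1",)
        assert pc.genes[0] == frozenset({"A", "B"})

    def test_gene_symbols_whitespace_trimmed(self, tmp_path):
        f = write(tmp_path / "p.gmt", "P1\td\t A \tB\n")
        assert ssn.load_pathways(f).genes[0] == frozenset({"A", "B"})

    @pytest.mark.parametrize("content,match", [
        ("", "no pathways"),
        ("P1\td\tA\nP1\td\tB\n", "duplicate pathway"),
        ("P1\td\t\n", "no genes"),
        ("P1\tA\n", "3 tab-separated"),
    ])
    def test_malformed_files_rejected(self, tmp_path, content, match):
        f = write(tmp_path / "bad.gmt", content)
        with pytest.raises(PathwayFileError, match=match):
            ssn.load_pathways(f)

    def test_order_stable_across_loads(self, tmp_path):
        f = write(tmp_path / "p.gmt", "B\td\tX\nA\td\tY\n")
        assert ssn.load_pathways(f).names == ssn.load_pathways(f).names == ("B", "A")


# ------------------------------------------------------------------ matrices

class TestLoadMatrix:
    def test_orientation_transposed_to_samples_by_genes(self, tmp_path):
        f = write(tmp_path / "m.tsv",
                  "sample\tS1\tS2\nG1\t1\t2\nG2\t3\t4\nG3\t5\t6\n")
        m = ssn.load_matrix(f)
        assert m.shape == (2, 3)
        assert list(m.index) == ["S1", "S2"]
        assert m.loc["S2", "G1"] == 2.0

    def test_integer_kind_rejects_fractional_values(self, tmp_path):
        f = write(tmp_path / "m.tsv", "sample\tS1\nG1\t0.5\n")
        with pytest.raises(MatrixFormatError, match="non-integral"):
            ssn.load_matrix(f, "integer")

    def test_duplicate_gene_rows_named_in_error(self, tmp_path):
        f = write(tmp_path / "m.tsv", "sample\tS1\nG1\t1\nG1\t2\n")
        with pytest.raises(MatrixFormatError, match="G1"):
            ssn.load_matrix(f)

    def test_non_numeric_cell_located_in_error(self, tmp_path):
        f = write(tmp_path / "m.tsv", "sample\tS1\tS2\nG1\t1\txx\n")
        with pytest.raises(MatrixFormatError, match="G1.*S2"):
            ssn.load_matrix(f)

    def test_write_then_load_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.standard_normal((4, 6)),
                         index=[f"S{i}" for i in range(4)],
                         columns=[f"G{j}" for j in range(6)])
        ssn.write_matrix(m, tmp_path / "m.tsv")
        back = ssn.load_matrix(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back, m, check_exact=True, check_names=False)


# ------------------------------------------------------------------ clinical

CLIN_HEADER = "sample_id\tage\tgender\tstage\tvital_status\tsurvival_days\n"


class TestLoadClinical:
    def test_stage_and_survival_parsed(self, tmp_path):
        f = write(tmp_path / "c.tsv",
                  CLIN_HEADER + "S1\t60\tfemale\tStage II\tdeceased\t1500\n")
        c = ssn.load_clinical(f)
        assert c.loc["S1", "stage_ordinal"] == 2
        assert c.loc["S1", "survival_days"] == 1500
        assert c.loc["S1", "vital_status"] == 1

    @pytest.mark.parametrize("raw,expected", [
        ("Stage I", 1), ("Stage IIb", 2), ("stage iiia", 3), ("Stage IV", 4)])
    def test_substages_collapse_to_parent(self, raw, expected):
        assert parse_stage(raw) == expected

    def test_missing_survival_rows_dropped_and_counted(self, tmp_path):
        f = write(tmp_path / "c.tsv",
                  CLIN_HEADER
                  + "S1\t60\tmale\tStage I\tliving\t900\n"
                  + "S2\t62\tmale\tStage I\tliving\t\n")
        c = ssn.load_clinical(f)
        assert list(c.index) == ["S1"]
        assert c.attrs["n_dropped_missing_survival"] == 1

    def test_unparsable_stages_flagged_and_imputed(self, tmp_path):
        rows = [f"S{i}\t60\tmale\tStage II\tliving\t{500 + i}" for i in range(8)]
        rows += ["S8\t61\tmale\tStage X\tliving\t800",
                 "S9\t62\tmale\t\tliving\t900"]
        f = write(tmp_path / "c.tsv", CLIN_HEADER + "\n".join(rows) + "\n")
        c = ssn.load_clinical(f)
        assert len(c) == 10
        assert c.attrs["n_stage_unknown"] == 2
        assert (c.loc[c["stage_unknown"], "stage_ordinal"] == 2).all()

    def test_missing_required_column_is_config_error(self, tmp_path):
        f = write(tmp_path / "c.tsv", "sample_id\tage\nS1\t60\n")
        with pytest.raises(ClinicalFormatError, match="missing required"):
            ssn.load_clinical(f)

    def test_custom_column_names_mapped(self, tmp_path):
        f = write(tmp_path / "c.tsv",
                  "id\tage\tgender\tstage\tvital_status\tdays\nS1\t60\tf\tStage I\tliving\t100\n")
        c = ssn.load_clinical(f, column_map={"sample_id": "id", "survival_days": "days"})
        assert c.loc["S1", "survival_days"] == 100


# ------------------------------------------------------------------ assembly

def toy_inputs(survivals=(100, 3000, 3001), n_genes=5, covered=3):
    """Tiny aligned expression/CNV/clinical trio plus a pathway collection
    covering only the first ``covered`` genes."""
    samples = [f"S{i}" for i in range(len(survivals))]
    genes = [f"G{j}" for j in range(n_genes)]
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.uniform(1, 5, (len(samples), n_genes)),
                        index=samples, columns=genes)
    cnv = pd.DataFrame(rng.integers(-2, 3, (len(samples), n_genes)),
                       index=samples, columns=genes, dtype=float)
    clinical = pd.DataFrame({
        "age": 60.0, "gender_code": 0, "stage_ordinal": 2.0,
        "stage_unknown": False, "vital_status": 1,
        "survival_days": list(survivals),
    }, index=samples)
    pathways = ssn.PathwayCollection(
        names=("PA", "PB"),
        genes=(frozenset(genes[:2]), frozenset(genes[2:covered])),
    )
    return expr, cnv, clinical, pathways


class TestAssembleDataset:
    def test_survival_cap_boundary_3000_kept_3001_dropped(self):
        expr, cnv, clin, pc = toy_inputs(survivals=(100, 3000, 3001))
        data, _ = ssn.assemble_dataset(expr, cnv, clin, pc)
        assert list(data.sample_ids) == ["S0", "S1"]
        assert data.exclusions["samples_survival_gt_3000"] == 1

    def test_gene_set_is_intersection_with_pathway_union(self):
        expr, cnv, clin, pc = toy_inputs(n_genes=5, covered=3)
        data, mask = ssn.assemble_dataset(expr, cnv, clin, pc)
        assert data.n_genes == 3
        assert mask.matrix.shape == (3, 2)

    def test_zero_expression_gene_filter_uses_training_partition_only(self):
        expr, cnv, clin, pc = toy_inputs(survivals=(100, 200, 300))
        expr.loc[["S0", "S1"], "G0"] = 0.0  # zero in training, nonzero in test
        data, mask = ssn.assemble_dataset(expr, cnv, clin, pc,
                                          training_samples=["S0", "S1"])
        assert "G0" not in data.gene_ids
        assert "G0" not in mask.gene_index
        assert data.exclusions["genes_zero_expression_in_training"] == 1

    def test_mask_faithful_to_membership(self):
        expr, cnv, clin, pc = toy_inputs()
        data, mask = ssn.assemble_dataset(expr, cnv, clin, pc)
        members = dict(zip(pc.names, pc.genes))
        for g, gene in enumerate(mask.gene_index):
            for p, pw in enumerate(mask.pathway_index):
                assert mask.matrix[g, p] == (1 if gene in members[pw] else 0)

    def test_assembly_idempotent(self):
        expr, cnv, clin, pc = toy_inputs()
        data, mask = ssn.assemble_dataset(expr, cnv, clin, pc)
        again, mask2 = ssn.assemble_dataset(
            data.expression, data.copy_number, data.clinical, pc)
        pd.testing.assert_frame_equal(again.expression, data.expression)
        pd.testing.assert_frame_equal(again.copy_number, data.copy_number)
        assert np.array_equal(mask2.matrix, mask.matrix)

    def test_pathway_left_without_genes_is_error(self):
        expr, cnv, clin, pc = toy_inputs()
        expr[["G2"]] = 0.0  # PB's only retained gene becomes all-zero
        with pytest.raises(AssemblyError, match="no retained genes"):
            ssn.assemble_dataset(expr, cnv, clin, pc)

    def test_disjoint_samples_is_error(self):
        expr, cnv, clin, pc = toy_inputs()
        clin.index = ["X0", "X1", "X2"]
        with pytest.raises(AssemblyError, match="no samples shared"):
            ssn.assemble_dataset(expr, cnv, clin, pc)
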