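import numpy as np
import pandas as pd
import pytest

import varcon
from varcon import ValidationError
from varcon.data_io import (
    write_annotations,
    write_expression_bundle,
    write_gene_sets,
    write_network,
)

from conftest import make_design


def _write_trio(tmp_path, expr, det, design):
    paths = {}
    for name, df in [("expr", expr), ("det", det), ("design", design)]:
        p = tmp_path / f"{name}.tsv"
        df.to_csv(p, sep="\t")
        paths[name] = p
    return paths


@pytest.fixture
def trio(tmp_path):
    samples = ["s0", "s1"]
    expr = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], index=["g0", "g1", "g2"], columns=samples
    )
    det = pd.DataFrame(0.005, index=expr.index, columns=samples)
    design = make_design(samples)
    return _write_trio(tmp_path, expr, det, design)


class TestExpressionBundle:
    def test_well_formed_round_trip(self, trio, tmp_path):
        bundle = varcon.read_expression_bundle(trio["expr"], trio["det"], trio["design"])
        assert bundle.expression.shape == (3, 2)
        out = write_expression_bundle(bundle, tmp_path / "rt")
        again = varcon.read_expression_bundle(out["expression"], out["detection"], out["design"])
        pd.testing.assert_frame_equal(bundle.expression, again.expression)
        pd.testing.assert_frame_equal(bundle.detection, again.detection)
        pd.testing.assert_frame_equal(bundle.design, again.design)

    def test_missing_detection_column_names_sample(self, trio, tmp_path):
        det = pd.read_csv(trio["det"], sep="\t", index_col=0).drop(columns=["s1"])
        det.to_csv(tmp_path / "det_bad.tsv", sep="\t")
        with pytest.raises(ValidationError, match="s1"):
            varcon.read_expression_bundle(trio["expr"], tmp_path / "det_bad.tsv", trio["design"])

    def test_replicate_counting(self, tmp_path):
        samples = [f"s{i}" for i in range(4)]
        expr = pd.DataFrame(np.ones((2, 4)), index=["g0", "g1"], columns=samples)
        det = pd.DataFrame(0.001, index=expr.index, columns=samples)
        design = make_design(samples, donors=["A"] * 4)
        paths = _write_trio(tmp_path, expr, det, design)
        bundle = varcon.read_expression_bundle(paths["expr"], paths["det"], paths["design"])
        assert bundle.replicate_counts()["A"] == 4

    def test_negative_intensity_rejected(self, trio, tmp_path):
        expr = pd.read_csv(trio["expr"], sep="\t", index_col=0)
        expr.iloc[0, 0] = -1.0
        expr.to_csv(tmp_path / "expr_bad.tsv", sep="\t")
        with pytest.raises(ValidationError, match="negative intensity"):
            varcon.read_expression_bundle(tmp_path / "expr_bad.tsv", trio["det"], trio["design"])

    def test_detection_out_of_range_rejected(self, trio, tmp_path):
        det = pd.read_csv(trio["det"], sep="\t", index_col=0)
        det.iloc[1, 1] = 1.5
        det.to_csv(tmp_path / "det_bad.tsv", sep="\t")
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            varcon.read_expression_bundle(trio["expr"], tmp_path / "det_bad.tsv", trio["design"])

    def test_missing_detection_allowed_with_none(self, trio):
        bundle = varcon.read_expression_bundle(trio["expr"], None, trio["design"])
        assert bundle.detection is None


class TestGeneSets:
    def test_intersection_with_universe(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tg1\tg2\tg3\n")
        coll = varcon.read_gene_sets(p, ["g1", "g2"])
        assert coll["S1"] == ["g1", "g2"]
        assert coll.original_sizes["S1"] == 3

    def test_empty_after_intersection_dropped(self, tmp_path, caplog):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tg1\nS2\tdesc\tgX\n")
        coll = varcon.read_gene_sets(p, ["g1"])
        assert coll.names() == ["S1"]

    def test_overlapping_sets_both_retained(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\td\tg1\tg2\nS2\td\tg2\tg3\n")
        coll = varcon.read_gene_sets(p, ["g1", "g2", "g3"])
        assert set(coll.names()) == {"S1", "S2"}
        assert "g2" in coll["S1"] and "g2" in coll["S2"]

    def test_duplicate_name_rejected(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\td\tg1\nS1\td\tg2\n")
        with pytest.raises(ValidationError, match="duplicate set name"):
            varcon.read_gene_sets(p, ["g1", "g2"])

    def test_short_line_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\td\tg1\nS2\n")
        with pytest.raises(ValidationError, match=":2"):
            varcon.read_gene_sets(p, ["g1"])

    def test_round_trip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tg1\tg2\n")
        coll = varcon.read_gene_sets(p, ["g1", "g2"])
        out = write_gene_sets(coll, tmp_path / "rt.gmt")
        again = varcon.read_gene_sets(out, ["g1", "g2"])
        assert again.sets == coll.sets


class TestNetwork:
    def test_dedupe_and_self_loop(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nB\tA\nA\tA\n")
        net = varcon.read_network(p)
        assert net.n_edges == 1 and net.n_nodes == 2

    def test_empty_file_gives_empty_network(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("")
        net = varcon.read_network(p)
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_sif_three_token_line(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A pp B\n")
        net = varcon.read_network(p)
        assert net.graph.has_edge("A", "B")

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nlonely\n")
        with pytest.raises(ValidationError, match=":2"):
            varcon.read_network(p)

    def test_round_trip(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\nC\tD\n")
        net = varcon.read_network(p)
        out = write_network(net, tmp_path / "rt.tsv")
        again = varcon.read_network(out)
        assert set(map(frozenset, again.graph.edges())) == set(map(frozenset, net.graph.edges()))


class TestAnnotations:
    def test_dedupe(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("g1\tT1\tBP\ng1\tT1\tBP\n")
        ann = varcon.read_annotations(p)
        assert len(ann) == 1

    def test_class_partitions(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("g1\tT1\tBP\ng2\tT2\tMF\n")
        ann = varcon.read_annotations(p)
        assert set(ann.classes()) == {"BP", "MF"}
        assert len(ann.by_class("BP")) == 1

    def test_counting_5_genes_2_terms(self, tmp_path):
        rows = [f"g{i}\tT{j}\tBP" for i in range(5) for j in range(2)]
        p = tmp_path / "ann.tsv"
        p.write_text("\n".join(rows) + "\n")
        assert len(varcon.read_annotations(p)) == 10

    def test_strict_class_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("g1\tT1\tXX\n")
        with pytest.raises(ValidationError, match="XX"):
            varcon.read_annotations(p, strict_classes=("BP", "MF", "CC"))

    def test_round_trip(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("g1\tT1\tBP\ng2\tT1\tBP\n")
        ann = varcon.read_annotations(p)
        out = write_annotations(ann, tmp_path / "rt.tsv")
        pd.testing.assert_frame_equal(varcon.read_annotations(out).records, ann.records)
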