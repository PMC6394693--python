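"""Matrix ingestion, log-CPM normalisation, z-scoring, gene sets, anchor curve."""

import numpy as np
import pandas as pd
import pytest

import synlet as sl
from synlet.expression_prep import ExpressionMatrix, write_gmt


class TestReadCounts:
    def test_toy_roundtrip(self, toy_counts):
        m = sl.read_counts(toy_counts)
        assert m.stage == "counts"
        assert m.values.loc["g2", "s2"] == 270

    def test_duplicate_rows_collapsed_by_sum(self, tmp_path, caplog):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\ts1\ng1\t3\ng1\t5\ng2\t7\n")
        with caplog.at_level("WARNING"):
            m = sl.read_counts(path)
        assert m.values.loc["g1", "s1"] == 8
        assert "duplicate" in caplog.text

    def test_non_numeric_cell_cited(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ng1\t3\tx\ng2\t7\t1\n")
        with pytest.raises(ValueError, match="g1.*s2"):
            sl.read_counts(path)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("gene\ts1\ng1\t-3\n")
        with pytest.raises(ValueError, match="negative"):
            sl.read_counts(path)


class TestNormalize:
    def test_cpm_boundary_inclusive(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [999_999.0, 1.0]}, index=["a", "b"]), stage="counts"
        )
        out = sl.normalize_counts(m, min_cpm=1, min_samples=1)
        assert list(out.values.index) == ["a", "b"]  # CPM of b is exactly 1

    def test_library_scaling_invariance(self):
        base = pd.DataFrame({"s1": [10.0, 90.0, 300.0]}, index=["a", "b", "c"])
        m = ExpressionMatrix(pd.concat([base["s1"], base["s1"] * 10], axis=1, keys=["s1", "s2"]), stage="counts")
        out = sl.normalize_counts(m)
        assert np.allclose(out.values["s1"], out.values["s2"])

    def test_matches_direct_formula(self, toy_counts):
        m = sl.read_counts(toy_counts)
        out = sl.normalize_counts(m)
        lib = m.values.sum(axis=0)
        expected = np.log2(m.values / lib * 1e6 + 0.5)
        assert np.allclose(out.values, expected.loc[out.values.index], atol=1e-9)

    def test_log_input_passthrough(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"]), stage="log_expression")
        assert sl.normalize_counts(m) is m

    def test_all_filtered_is_error(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [10.0], "s2": [10.0]}, index=["a"]), stage="counts"
        )
        with pytest.raises(ValueError, match="all genes"):
            sl.normalize_counts(m, min_cpm=1e9, min_samples=1)

    def test_tmm_neutral_on_proportional_libraries(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, 200).astype(float) + 1
        df = pd.DataFrame({"s1": base, "s2": base * 3}, index=[f"g{i}" for i in range(200)])
        m = ExpressionMatrix(df, stage="counts")
        plain = sl.normalize_counts(m)
        tmm = sl.normalize_counts(m, use_tmm=True)
        assert np.allclose(plain.values, tmm.values, atol=1e-6)


class TestStandardize:
    def test_known_zscores(self):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc")),
            stage="log_expression",
        )
        out = sl.standardize_genes(m)
        assert np.allclose(out.values.loc["g"], [-1.224744871, 0.0, 1.224744871])

    def test_constant_row_dropped(self, caplog):
        m = ExpressionMatrix(
            pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "g"]),
            stage="log_expression",
        )
        with caplog.at_level("WARNING"):
            out = sl.standardize_genes(m)
        assert list(out.values.index) == ["g"]
        assert "constant" in caplog.text

    def test_moments_and_idempotence(self):
        rng = np.random.default_rng(1)
        m = ExpressionMatrix(
            pd.DataFrame(rng.normal(5, 2, (20, 30))), stage="log_expression"
        )
        z = sl.standardize_genes(m)
        assert np.allclose(z.values.to_numpy().mean(axis=1), 0, atol=1e-8)
        assert np.allclose(z.values.to_numpy().std(axis=1), 1, atol=1e-8)
        z2 = sl.standardize_genes(z)
        assert np.allclose(z.values, z2.values, atol=1e-8)


class TestGeneSets:
    def _write(self, tmp_path, lines):
        path = tmp_path / "sets.gmt"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_size_filter_after_universe_intersection(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                "keep\tna\tg1\tg2\tg3\tg4\tg5",
                "drop\tna\tg1\tg2\tg3\tx1\tx2\tx3\tx4",
            ],
        )
        universe = [f"g{i}" for i in range(1, 6)]
        sets = sl.read_gene_sets(path, min_size=5, universe=universe)
        assert list(sets) == ["keep"]

    def test_duplicate_members_deduplicated(self, tmp_path):
        path = self._write(tmp_path, ["s\tna\ta\tb\ta\tc"])
        sets = sl.read_gene_sets(path, min_size=1)
        assert sets["s"] == ("a", "b", "c")

    def test_malformed_line_cites_number(self, tmp_path):
        path = self._write(tmp_path, ["ok\tna\ta\tb", "broken_line"])
        with pytest.raises(ValueError, match=":2"):
            sl.read_gene_sets(path, min_size=1)

    def test_universe_shrink_monotone(self, tmp_path):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        lines = [
            f"s{j}\tna\t" + "\t".join(rng.choice(genes, 10, replace=False))
            for j in range(15)
        ]
        path = self._write(tmp_path, lines)
        big = sl.read_gene_sets(path, min_size=5, universe=genes)
        small = sl.read_gene_sets(path, min_size=5, universe=genes[:25])
        assert set(small).issubset(set(big))

    def test_gmt_roundtrip(self, tmp_path):
        sets = sl.GeneSetCollection({"s1": ("a", "b", "c")}, provenance="test")
        out = tmp_path / "round.gmt"
        write_gmt(sets, out)
        back = sl.read_gene_sets(out, min_size=1)
        assert back["s1"] == ("a", "b", "c")


class TestAnchorProfile:
    @staticmethod
    def _matrix(anchor_vals):
        df = pd.DataFrame(
            [anchor_vals, np.zeros(len(anchor_vals)) + 1.5],
            index=["CDH1", "other"],
            columns=[f"t{i}" for i in range(len(anchor_vals))],
        )
        return ExpressionMatrix(df, stage="log_expression")

    def test_constant_anchor_flat_curve(self):
        prof = sl.anchor_profile(self._matrix([2.0] * 12), "CDH1")
        assert prof.ratio_at_rank(0.1) == pytest.approx(1.0)
        assert prof.ratio_at_rank(0.9) == pytest.approx(1.0)

    def test_linear_ladder(self):
        vals = np.log2(np.arange(1, 11, dtype=float))
        prof = sl.anchor_profile(self._matrix(vals), "CDH1")
        assert prof.ratio_at_rank(0.10) == pytest.approx(1 / 5.5, abs=1e-9)

    def test_absent_anchor_rejected(self):
        with pytest.raises(ValueError, match="MISSING"):
            sl.anchor_profile(self._matrix([1.0] * 10), "MISSING")
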