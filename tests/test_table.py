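import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_records, random_regions
from oracles import brute_force_scores

from mtable.annotation import Region
from mtable.errors import FormatError, ValidationError
from mtable.methio import CytosineRecord
from mtable.table import (
    SCORE_COLUMNS,
    MTable,
    read_mtable,
    score_methylation,
    to_matrix,
    write_mtable,
)


def _records_in(region, specs, context="CG"):
    """Records at consecutive positions inside a region; specs = (meth, unmeth)."""
    return [
        CytosineRecord(region.chrom, region.start + i, "+", m, u, context)
        for i, (m, u) in enumerate(specs)
    ]


BODY = Region("chr1", 1000, 2000, "body", "g1")
PROMOTER = Region("chr1", 500, 1000, "promoter", "g1")


class TestScoreMethylation:
    def test_weighted_level_pools_counts(self):
        records = _records_in(BODY, [(3, 1), (1, 3)])
        table = score_methylation(records, [PROMOTER, BODY])
        assert table.score("g1", "body", "CG") == pytest.approx(4 / 8)

    def test_fully_methylated_region_scores_one(self):
        records = _records_in(BODY, [(4, 0), (7, 0)])
        table = score_methylation(records, [PROMOTER, BODY])
        assert table.score("g1", "body", "CG") == 1.0

    def test_uncovered_context_is_missing(self):
        records = _records_in(BODY, [(3, 1)], context="CG")
        table = score_methylation(records, [PROMOTER, BODY])
        assert math.isnan(table.score("g1", "promoter", "CHH"))
        assert math.isnan(table.score("g1", "body", "CHG"))

    def test_min_coverage_excludes_thin_sites(self):
        records = _records_in(BODY, [(1, 0), (5, 5)])
        table = score_methylation(records, [BODY], min_coverage=4)
        assert table.score("g1", "body", "CG") == pytest.approx(0.5)

    def test_boundary_half_open(self):
        inside = CytosineRecord("chr1", 1000, "+", 1, 0, "CG")
        outside = CytosineRecord("chr1", 2000, "+", 0, 1, "CG")
        table = score_methylation([inside, outside], [BODY])
        assert table.score("g1", "body", "CG") == 1.0

    def test_absent_chromosome_gives_missing_not_error(self):
        records = [CytosineRecord("chrX", 1500, "+", 3, 1, "CG")]
        table = score_methylation(records, [BODY])
        assert math.isnan(table.score("g1", "body", "CG"))

    def test_empty_region_set_is_an_error(self):
        with pytest.raises(ValidationError, match="empty region"):
            score_methylation([], [])

    def test_site_mean_variant_averages_per_site_fractions(self):
        records = _records_in(BODY, [(3, 1), (1, 3)])
        table = score_methylation(records, [BODY], site_mean=True)
        assert table.score("g1", "body", "CG") == pytest.approx((0.75 + 0.25) / 2)

    def test_overlapping_genes_both_scored(self):
        other = Region("chr1", 1500, 2500, "body", "g2")
        records = _records_in(BODY, [(1, 1)]) + [
            CytosineRecord("chr1", 1600, "+", 3, 0, "CG")
        ]
        table = score_methylation(records, [BODY, other])
        assert table.score("g1", "body", "CG") == pytest.approx(4 / 5)
        assert table.score("g2", "body", "CG") == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_inputs(self, seed):
        rng = np.random.default_rng(900 + seed)
        records = random_records(rng, int(rng.integers(1, 50)))
        regions = random_regions(rng)
        min_coverage = int(rng.integers(0, 4))
        table = score_methylation(records, regions, min_coverage)
        expected = brute_force_scores(records, regions, min_coverage)
        for gene in table.gene_ids:
            for column in SCORE_COLUMNS:
                kind, context = column.split("_")
                got = table.score(gene, kind, context)
                want = expected.get((gene, kind, context))
                if want is None:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_to_record_order_and_splitting(self, rng):
        records = _records_in(BODY, [(6, 2), (2, 2)])
        split = _records_in(BODY, [(3, 1), (2, 2)]) + [
            CytosineRecord(BODY.chrom, BODY.start, "+", 3, 1, "CG")
        ]
        shuffled = list(records)
        rng.shuffle(shuffled)
        level = score_methylation(records, [BODY]).score("g1", "body", "CG")
        assert score_methylation(shuffled, [BODY]).score(
            "g1", "body", "CG"
        ) == pytest.approx(level)
        assert score_methylation(split, [BODY]).score(
            "g1", "body", "CG"
        ) == pytest.approx(level)

    def test_level_monotone_in_added_extreme_records(self):
        base = _records_in(BODY, [(3, 5)])
        level = score_methylation(base, [BODY]).score("g1", "body", "CG")
        plus_meth = base + [CytosineRecord("chr1", 1999, "+", 5, 0, "CG")]
        plus_unmeth = base + [CytosineRecord("chr1", 1999, "+", 0, 5, "CG")]
        assert score_methylation(plus_meth, [BODY]).score(
            "g1", "body", "CG") >= level
        assert score_methylation(plus_unmeth, [BODY]).score(
            "g1", "body", "CG") <= level


def _random_table(rng, genes, sample):
    values = rng.uniform(0, 1, size=(len(genes), 6))
    mask = rng.uniform(size=values.shape) < 0.2
    values[mask] = np.nan
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=list(SCORE_COLUMNS))
    return MTable(data, sample=sample, metadata={"min_coverage": 1})


class TestMtableFormat:
    def test_written_rows_have_exactly_seven_fields(self, tmp_path, rng):
        table = _random_table(rng, [f"g{i}" for i in range(10)], "s1")
        path = tmp_path / "t.mtable"
        write_mtable(table, path)
        data_lines = [
            l for l in path.read_text().splitlines() if not l.startswith("#")
        ]
        assert len(data_lines) == 10
        assert all(len(l.split("\t")) == 7 for l in data_lines)

    def test_all_missing_row_serializes_as_na(self, tmp_path):
        data = pd.DataFrame([[np.nan] * 6], index=["gid"],
                            columns=list(SCORE_COLUMNS))
        path = tmp_path / "na.mtable"
        write_mtable(MTable(data), path)
        row = [l for l in path.read_text().splitlines()
               if not l.startswith("#")][0]
        assert row == "gid\tNA\tNA\tNA\tNA\tNA\tNA"

    def test_round_trip_identity(self, tmp_path, rng):
        table = _random_table(rng, [f"g{i}" for i in range(25)], "sampleX")
        path = tmp_path / "rt.mtable"
        write_mtable(table, path)
        back = read_mtable(path)
        assert back.sample == "sampleX"
        # 6-decimal serialization: equal to printed precision
        pd.testing.assert_frame_equal(back.data, table.data.round(6),
                                      atol=1e-9, rtol=0)

    def test_read_parses_scores_and_na(self, tmp_path):
        path = tmp_path / "one.mtable"
        path.write_text("g1\t0.5\t0.25\tNA\t0.8\t0.1\t0.0\n")
        table = read_mtable(path)
        assert table.score("g1", "promoter", "CG") == 0.5
        assert math.isnan(table.score("g1", "promoter", "CHH"))
        assert table.score("g1", "body", "CHH") == 0.0

    def test_wrong_field_count_rejected(self, tmp_path):
        path = tmp_path / "bad.mtable"
        path.write_text("g1\t0.5\t0.25\tNA\t0.8\t0.1\n")
        with pytest.raises(FormatError, match="7"):
            read_mtable(path)

    def test_out_of_range_score_rejected(self, tmp_path):
        path = tmp_path / "bad.mtable"
        path.write_text("g1\t1.2\t0.2\t0.2\t0.2\t0.2\t0.2\n")
        with pytest.raises(ValidationError, match=r"outside \[0, 1\]"):
            read_mtable(path)


class TestToMatrix:
    def test_shared_gene_row_spans_samples(self, rng):
        t1 = _random_table(rng, ["g1", "g2"], "a")
        t2 = _random_table(rng, ["g1", "g3"], "b")
        matrix = to_matrix([t1, t2], "CG", "body")
        assert list(matrix.columns) == ["a", "b"]
        assert list(matrix.index) == ["g1", "g2", "g3"]
        assert matrix.at["g1", "a"] == t1.score("g1", "body", "CG") or (
            math.isnan(matrix.at["g1", "a"])
            and math.isnan(t1.score("g1", "body", "CG"))
        )
        assert math.isnan(matrix.at["g2", "b"])
        assert math.isnan(matrix.at["g3", "a"])

    def test_single_table_matrix_equals_its_column(self, rng):
        t = _random_table(rng, ["g1", "g2"], "only")
        matrix = to_matrix([t], "CHG", "promoter")
        pd.testing.assert_series_equal(
            matrix["only"], t.column("promoter", "CHG"), check_names=False
        )

    def test_duplicate_sample_names_rejected(self, rng):
        t1 = _random_table(rng, ["g1"], "same")
        t2 = _random_table(rng, ["g2"], "same")
        with pytest.raises(ValidationError, match="duplicate sample"):
            to_matrix([t1, t2], "CG", "body")
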