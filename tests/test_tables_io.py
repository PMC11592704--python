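import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssipscore import tables_io
from ssipscore.tables_io import (
    PredictorConfig,
    TableFormatError,
    VariantKey,
    read_allele_counts,
    read_clin_labels,
    read_score_matrix,
    read_results,
    write_results,
)


@pytest.fixture
def pred_config():
    return PredictorConfig(direction={"A": 1, "B": -1}, exclude=("LINSIGHT",))


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestScoreMatrix:
    def test_missing_cells_parsed(self, tmp_path, pred_config):
        path = _write(tmp_path, "m.tsv",
                      "variant\tA\tB\nV1\t0.5\t0.1\nV2\t.\t0.2\nV3\t0.9\t0.3\n")
        m = read_score_matrix(path, pred_config)
        assert m.scores.isna().sum().sum() == 1
        assert np.isnan(m.scores.loc["V2", "A"])

    def test_multivalue_collapses_to_most_deleterious(self, tmp_path, pred_config):
        path = _write(tmp_path, "m.tsv",
                      "variant\tA\tB\nV1\t0.91;0.88\t0.3;0.1\nV2\t0.5\t0.2\n")
        m = read_score_matrix(path, pred_config)
        assert m.scores.loc["V1", "A"] == 0.91  # direction +1 -> max
        assert m.scores.loc["V1", "B"] == 0.1  # direction -1 -> min

    def test_excluded_column_dropped_unknown_rejected(self, tmp_path, pred_config):
        path = _write(tmp_path, "m.tsv",
                      "variant\tA\tB\tLINSIGHT\nV1\t0.5\t0.1\t0.3\n")
        m = read_score_matrix(path, pred_config)
        assert m.predictors == ["A", "B"]
        bad = _write(tmp_path, "bad.tsv", "variant\tA\tMystery\nV1\t0.5\t0.1\n")
        with pytest.raises(TableFormatError, match="Mystery"):
            read_score_matrix(bad, pred_config)
        m2 = read_score_matrix(bad, pred_config, on_unknown="drop")
        assert m2.predictors == ["A"]

    def test_non_numeric_cell_names_row_and_column(self, tmp_path, pred_config):
        path = _write(tmp_path, "m.tsv", "variant\tA\tB\nV9\toops\t0.1\n")
        with pytest.raises(TableFormatError, match="V9.*A|A.*V9"):
            read_score_matrix(path, pred_config)

    def test_variant_key_invariants(self):
        with pytest.raises(TableFormatError):
            VariantKey(label="x", pos=0)
        with pytest.raises(TableFormatError):
            VariantKey(label="x", ref="A", alt="A")


class TestClinLabels:
    TABLE = (
        "variant\tsignificance\treview_stars\tsource_flags\n"
        "V1\tPathogenic\t2\t\n"
        "V2\tLikely benign\t1\t\n"
        "V3\tUncertain significance\t0\tSimpleClinVar\n"
        "V4\tdrug response\t3\t\n"
        "V5\tBenign/Likely benign\t3\t\n"
    )

    def test_group_mapping_and_star_filter(self, tmp_path):
        path = _write(tmp_path, "c.tsv", self.TABLE)
        labels = read_clin_labels(path, min_stars=2)
        assert labels.groups.to_dict() == {
            "V1": "Pathogenic", "V3": "Unknown", "V5": "Benign"}
        assert "V2" not in labels.groups.index  # one star, no flag
        assert labels.n_skipped == 1  # unmappable significance
        assert labels.provenance.loc["V3", "retained_by"] == "flag"


class TestAlleleCounts:
    def test_thousands_separators_and_na(self, tmp_path):
        path = _write(tmp_path, "a.tsv",
                      "variant\tcohort_alt\tcohort_total\tcohort_hom\tref_alt\tref_total\tref_hom\n"
                      "V1\t18\t3414\t0\t644\t1,595,894\t1\n"
                      "V5\t1\t3414\t0\tNA\tNA\tNA\n")
        t = read_allele_counts(path)
        assert t.references == ["ref"]
        assert t.df.loc[0, "ref_total"] == 1595894
        assert pd.isna(t.df.loc[1, "ref_alt"])

    @pytest.mark.parametrize("row,msg", [
        ("V1\t10\t5\t0\t1\t10\t0", "exceeds total"),
        ("V1\t-1\t5\t0\t1\t10\t0", "negative"),
        ("V1\t4\t5\t3\t1\t10\t0", "homozygote"),
    ])
    def test_invalid_counts_rejected(self, tmp_path, row, msg):
        path = _write(tmp_path, "a.tsv",
                      "variant\tcohort_alt\tcohort_total\tcohort_hom\tref_alt\tref_total\tref_hom\n"
                      + row + "\n")
        with pytest.raises(TableFormatError, match=msg):
            read_allele_counts(path)

    @given(rows=st.lists(
        st.tuples(st.integers(0, 100), st.integers(0, 1000), st.booleans()),
        min_size=1, max_size=12))
    def test_missing_never_coerced_to_zero(self, rows, tmp_path_factory):
        """Injected NA reference cells must survive the round trip as NA."""
        tmp = tmp_path_factory.mktemp("ac")
        lines = ["variant\tcohort_alt\tcohort_total\tref_alt\tref_total"]
        for i, (alt, extra, missing) in enumerate(rows):
            ref = "NA\tNA" if missing else f"{alt}\t{alt + extra}"
            lines.append(f"V{i+1}\t{alt}\t{alt + extra + 3414}\t{ref}")
        path = tmp / "a.tsv"
        path.write_text("\n".join(lines) + "\n")
        t = read_allele_counts(path)
        for i, (_, _, missing) in enumerate(rows):
            assert pd.isna(t.df.loc[i, "ref_alt"]) == missing


class TestResultsRoundTrip:
    def test_round_trip_identity(self, tmp_path, tv_results):
        path = tmp_path / "r.tsv"
        write_results(tv_results, path)
        back = read_results(path)
        again = tmp_path / "r2.tsv"
        write_results(back, again)
        assert path.read_text() == again.read_text()  # stable after one cycle
        pd.testing.assert_series_equal(
            back["raw_p"], tv_results["raw_p"], rtol=1e-8, check_names=False)

    def test_nine_digit_serialization(self, tmp_path):
        df = pd.DataFrame({"variant": ["V32"], "adj_p": [0.0876602790022]})
        path = tmp_path / "p.tsv"
        write_results(df, path)
        assert "0.087660279" in path.read_text()

    def test_empty_results_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["variant", "raw_p"])
        path = tmp_path / "e.tsv"
        write_results(df, path)
        assert path.read_text().strip() == "variant\traw_p"
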