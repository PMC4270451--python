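"""Study-table I/O and the ordered inclusion rules."""

import math

import pytest

from hetmeta.schema import (
    CSV_COLUMNS,
    ArmSummary,
    MetaAnalysis,
    SchemaError,
    Setting,
    StudyRecord,
    read_study_table,
    write_study_table,
)
from hetmeta.simulate import default_config, generate_dataset

HEADER = ",".join(CSV_COLUMNS)


def row(ma="M1", study="S1", sub=1, sd1="1.0", sd2="1.0", n1=10, n2=10,
        outcome="mental_health", comparison="pharm_vs_placebo", area="digestive"):
    return (f"R1,C1,{ma},{study},{sub},{n1},0.5,{sd1},{n2},0.0,{sd2},"
            f"{outcome},{comparison},{area}")


def write(tmp_path, lines, name="t.csv"):
    path = tmp_path / name
    path.write_text("\n".join([HEADER] + lines) + "\n")
    return path


class TestReading:
    def test_clean_file_loads_without_exclusions(self, tmp_path):
        path = write(tmp_path, [row(study=f"S{i}") for i in range(4)])
        collection, report = read_study_table(path)
        assert len(collection) == 1
        assert len(collection[0]) == 4
        assert report.empty
        assert collection[0].setting == Setting(
            "mental_health", "pharm_vs_placebo", "digestive"
        )

    def test_missing_sd_drops_study_then_undersized_ma(self, tmp_path):
        path = write(tmp_path, [row(study="S1"), row(study="S2", sd1="")])
        collection, report = read_study_table(path)
        assert collection == []
        assert report.n_missing_sd == 1
        assert report.n_undersized_mas == 1
        assert report.n_undersized_studies == 1

    def test_zero_sd_counts_as_missing(self, tmp_path):
        path = write(tmp_path, [row(study=f"S{i}") for i in range(3)]
                     + [row(study="S9", sd2="0.0")])
        _, report = read_study_table(path)
        assert report.n_missing_sd == 1
        assert report.n_retained == 3

    def test_single_participant_arm_rejected(self, tmp_path):
        path = write(tmp_path, [row(study=f"S{i}") for i in range(2)]
                     + [row(study="S9", n2=1)])
        collection, report = read_study_table(path)
        assert report.n_small_arm == 1
        assert len(collection[0]) == 2

    def test_duplicate_across_subgroups_keeps_first(self, tmp_path):
        path = write(tmp_path, [row(study="S1", sub=1), row(study="S2", sub=1),
                                row(study="S1", sub=2)])
        collection, report = read_study_table(path)
        assert report.n_duplicate == 1
        assert len(collection[0]) == 2
        assert collection[0].studies[0].subgroup_index == 1

    def test_other_outcome_meta_analysis_excluded(self, tmp_path):
        path = write(tmp_path, [row(study=f"S{i}", outcome="other")
                                for i in range(3)])
        collection, report = read_study_table(path)
        assert collection == []
        assert report.n_other_outcome_mas == 1
        assert report.n_other_outcome_studies == 3

    def test_exclusion_accounting_is_complete(self, tmp_path):
        lines = ([row(study=f"S{i}") for i in range(3)]
                 + [row(study="S3", sd1=""), row(study="S0", sub=2),
                    row(ma="M2", study="T1"),
                    row(ma="M3", study="U1", outcome="other"),
                    row(ma="M3", study="U2", outcome="other")])
        _, report = read_study_table(path := write(tmp_path, lines))
        report.check()
        total = (report.n_retained + report.n_missing_sd + report.n_small_arm
                 + report.n_duplicate + report.n_undersized_studies
                 + report.n_other_outcome_studies + report.n_skipped)
        assert total == report.n_rows == 8

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(SchemaError, match="header"):
            read_study_table(path)

    def test_malformed_numeric_names_line(self, tmp_path):
        path = write(tmp_path, [row(study="S1"), row(study="S2").replace("10,0.5", "xx,0.5")])
        with pytest.raises(SchemaError, match="line 3"):
            read_study_table(path)

    def test_unknown_label_strict_raises_lenient_skips(self, tmp_path):
        path = write(tmp_path, [row(study=f"S{i}") for i in range(2)]
                     + [row(study="S9", area="astrology")])
        with pytest.raises(SchemaError, match="astrology"):
            read_study_table(path, strict=True)
        with pytest.warns(UserWarning, match="astrology"):
            collection, report = read_study_table(path, strict=False)
        assert report.n_skipped == 1
        assert len(collection[0]) == 2


class TestRoundTrip:
    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_study_table([], path)
        assert path.read_text().strip() == HEADER
        collection, report = read_study_table(path)
        assert collection == [] and report.n_rows == 0

    def test_single_ma_round_trip_identity(self, tmp_path):
        src = write(tmp_path, [row(study=f"S{i}") for i in range(3)])
        collection, _ = read_study_table(src)
        out = tmp_path / "rt.csv"
        write_study_table(collection, out)
        again, report = read_study_table(out)
        assert again == collection and report.empty

    def test_synthetic_500_ma_round_trip_identity(self, tmp_path):
        ds = generate_dataset(default_config(seed=1, n_meta_analyses=500))
        out = tmp_path / "big.csv"
        write_study_table(ds.collection, out)
        again, report = read_study_table(out)
        assert report.empty
        assert again == ds.collection


class TestTypes:
    def test_arm_invariants(self):
        with pytest.raises(SchemaError):
            ArmSummary(n=0, mean=0.0, sd=1.0)
        with pytest.raises(SchemaError):
            ArmSummary(n=5, mean=0.0, sd=-1.0)

    def test_meta_analysis_needs_two_distinct_studies(self):
        s = StudyRecord("r", "c", "m", "s", ArmSummary(5, 0.0, 1.0),
                        ArmSummary(5, 0.0, 1.0))
        setting = Setting("obstetric", "pharm_vs_pharm", "cardiovascular")
        with pytest.raises(SchemaError, match=">= 2"):
            MetaAnalysis("r", "c", "m", setting, (s,))
        with pytest.raises(SchemaError, match="duplicated"):
            MetaAnalysis("r", "c", "m", setting, (s, s))

    def test_setting_vocabulary_closed(self):
        with pytest.raises(SchemaError):
            Setting("other", "pharm_vs_pharm", "cardiovascular")
        with pytest.raises(SchemaError):
            Setting("obstetric", "pharm_vs_surgery", "cardiovascular")
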