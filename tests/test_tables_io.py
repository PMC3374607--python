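"""Table reading, taxonomic binning, depth filtering, alignment."""

import numpy as np
import pandas as pd
import pytest

from permcomp import tables_io
from permcomp.tables_io import (
    CATEGORIES,
    SchemaError,
    ValidationError,
    align_tables,
    bin_lineages,
    canonicalize,
    filter_min_reads,
    read_counts,
    read_metadata,
    read_qpcr,
)


def write_metadata_csv(tmp_path, rows, name="meta.csv"):
    path = tmp_path / name
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


GOOD_ROW = dict(
    subject_id="s1", phenotype="ileal_CD", nod2="R", atg16l1="NR/NR",
    gender="male", race="caucasian", age=35.0, smoker=True, cdiff=False,
    bmi=24.0, asa5=True, steroids=False, immunomodulators=False,
    anti_tnf="never",
)


class TestReadMetadata:
    def test_well_formed_rows(self, tmp_path):
        rows = [dict(GOOD_ROW, subject_id=f"s{i}") for i in range(3)]
        meta = read_metadata(write_metadata_csv(tmp_path, rows))
        assert len(meta) == 3
        assert meta.loc["s0", "phenotype"] == "ileal_CD"
        assert meta.loc["s0", "smoker"] is True

    def test_missing_phenotype_column_is_schema_error(self, tmp_path):
        rows = [{k: v for k, v in GOOD_ROW.items() if k != "phenotype"}]
        with pytest.raises(SchemaError, match="phenotype"):
            read_metadata(write_metadata_csv(tmp_path, rows))

    def test_negative_age_is_validation_error(self, tmp_path):
        rows = [GOOD_ROW, dict(GOOD_ROW, subject_id="s2", age=-5)]
        with pytest.raises(ValidationError, match="age"):
            read_metadata(write_metadata_csv(tmp_path, rows))

    def test_duplicate_subject_id_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="duplicate"):
            read_metadata(write_metadata_csv(tmp_path, [GOOD_ROW, GOOD_ROW]))

    def test_bad_enum_level_rejected(self, tmp_path):
        rows = [dict(GOOD_ROW, anti_tnf="sometimes")]
        with pytest.raises(ValidationError, match="anti_tnf"):
            read_metadata(write_metadata_csv(tmp_path, rows))


class TestBinLineages:
    def test_phylum_level_and_firmicutes_split(self):
        rows = pd.DataFrame(
            {
                "subject_id": ["a", "a", "a", "a", "a"],
                "phylum": ["Proteobacteria", "Firmicutes", "Firmicutes",
                           "Fusobacteria", "Bacteroidetes"],
                "group": [None, "Clostridium XIVa", "Lachnospiraceae", None, None],
            }
        )
        counts = bin_lineages(rows)
        assert counts.loc["a", "Proteobacteria"] == 1
        assert counts.loc["a", "Firmicutes_ClostridiumXIVa"] == 2
        assert counts.loc["a", "Other"] == 1  # Fusobacteria falls through
        assert counts.loc["a", "Bacteroidetes"] == 1

    def test_binning_is_total(self, rng):
        """Every row lands in exactly one category: column sums of the
        output equal the input row count per subject."""
        phyla = ["Firmicutes", "Proteobacteria", "Bacteroidetes",
                 "Actinobacteria", "Fusobacteria", "", "Verrucomicrobia"]
        groups = ["Clostridium IV", "Bacilli", "unknown thing", None]
        n = 500
        rows = pd.DataFrame(
            {
                "subject_id": rng.choice(["a", "b", "c"], size=n),
                "phylum": rng.choice(phyla, size=n),
                "group": rng.choice(groups, size=n),
            }
        )
        counts = bin_lineages(rows)
        assert list(counts.columns) == list(CATEGORIES)
        totals = rows.groupby("subject_id").size()
        assert (counts.sum(axis=1) == totals.reindex(counts.index)).all()

    def test_canonicalization_is_case_and_punctuation_insensitive(self):
        assert canonicalize("Clostridium Group XIVa") == canonicalize(
            "clostridium_group-XIVA"
        )
        rows = pd.DataFrame(
            {"subject_id": ["a"], "phylum": ["FIRMICUTES"], "group": ["ruminococcaceae"]}
        )
        assert bin_lineages(rows).loc["a", "Firmicutes_ClostridiumIV"] == 1


class TestFilterMinReads:
    def make_table(self, totals):
        rows = []
        for total in totals:
            row = np.zeros(7, dtype=int)
            row[5] = total
            rows.append(row)
        return pd.DataFrame(
            rows, columns=list(CATEGORIES),
            index=[f"s{i}" for i in range(len(totals))],
        )

    def test_strict_boundary(self):
        table = self.make_table([99, 100, 101])
        kept = filter_min_reads(table)
        assert list(kept.index) == ["s1", "s2"]  # 99 removed, 100 retained

    def test_identity_when_all_pass_and_idempotent(self):
        table = self.make_table([150, 200])
        once = filter_min_reads(table)
        pd.testing.assert_frame_equal(once, table)
        pd.testing.assert_frame_equal(filter_min_reads(once), once)

    def test_empty_result_allowed(self):
        assert len(filter_min_reads(self.make_table([1, 2]))) == 0


class TestAlignTables:
    def test_identical_subjects_intersection(self, small_cohort):
        aligned = align_tables(small_cohort.metadata, small_cohort.counts)
        platform = next(iter(small_cohort.counts))
        assert aligned.complete_cases == sorted(small_cohort.counts[platform].index)

    def test_missing_subjects_shrink_complete_cases(self, small_cohort):
        counts = dict(small_cohort.counts)
        platform = next(iter(counts))
        dropped = counts[platform].index[:5]
        counts[platform] = counts[platform].drop(dropped)
        aligned = align_tables(small_cohort.metadata, counts)
        expected = sorted(set(small_cohort.metadata.index) - set(dropped))
        assert aligned.complete_cases == expected
        assert aligned.exclusions[platform] == 5

    def test_matches_set_algebra_oracle(self, null_cohort, rng):
        counts = {}
        for platform, table in null_cohort.counts.items():
            drop = rng.choice(table.index, size=rng.integers(0, 20), replace=False)
            counts[platform] = table.drop(drop)
        aligned = align_tables(null_cohort.metadata, counts)
        oracle = set(null_cohort.metadata.index)
        for table in counts.values():
            oracle &= set(table.index)
        assert aligned.complete_cases == sorted(oracle)
        # output ids sorted and identical across joined tables
        for meta_p, counts_p in aligned.per_platform.values():
            assert list(meta_p.index) == sorted(meta_p.index)
            assert list(meta_p.index) == list(counts_p.index)

    def test_empty_intersection_raises(self, small_cohort):
        counts = {
            "sanger": small_cohort.counts["sanger"].set_index(
                pd.Index([f"x{i}" for i in range(len(small_cohort.metadata))],
                         name="subject_id")
            )
        }
        with pytest.raises(ValidationError):
            align_tables(small_cohort.metadata, counts)


class TestReadersRoundTrip:
    def test_counts_reader_validates(self, tmp_path):
        path = tmp_path / "c.tsv"
        df = pd.DataFrame([[1] * 7], columns=list(CATEGORIES))
        df.insert(0, "subject_id", ["a"])
        df.to_csv(path, sep="\t", index=False)
        counts = read_counts(path, platform="sanger")
        assert counts.attrs["platform"] == "sanger"
        df["Actinobacteria"] = [-1]
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError):
            read_counts(path)

    def test_qpcr_clamps_above_one(self, tmp_path, caplog):
        path = tmp_path / "q.csv"
        pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "target": ["f_prausnitzii"] * 2,
                "relative_frequency": [0.5, 1.3],
            }
        ).to_csv(path, index=False)
        with caplog.at_level("WARNING", logger="permcomp.tables_io"):
            table = read_qpcr(path)
        assert table["relative_frequency"].tolist() == [0.5, 1.0]
        assert any("clamped" in r.message for r in caplog.records)
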