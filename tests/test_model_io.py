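"""Domain types, VCF union-merge semantics, masking and table round trips."""

import numpy as np
import pandas as pd
import pytest

from linevar.config import AnalysisConfig
from linevar.io import (
    load_cohort,
    read_table,
    repetitive_mask,
    write_table,
    write_vcf,
)
from linevar.model import DepthTable, LineGenotypes, RecombinationMap, VariantKey


class TestVariantKey:
    def test_valid_key_and_id_round_trip(self):
        v = VariantKey("1", 100, "A", "T")
        assert VariantKey.from_id(v.variant_id) == v

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="1", pos=0, ref="A", alt="T"),
            dict(chrom="1", pos=5, ref="A", alt="A"),
            dict(chrom="1", pos=5, ref="A", alt="T,G"),
        ],
    )
    def test_invalid_keys_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariantKey(**kwargs)


class TestLineGenotypes:
    def test_dosage_bounds_enforced(self):
        with pytest.raises(ValueError):
            LineGenotypes("A", ["i1"], np.array([[2.5]]))

    def test_column_count_must_match_individuals(self):
        with pytest.raises(ValueError):
            LineGenotypes("A", ["i1", "i2"], np.zeros((3, 1)))


def _write_simple_vcf(path, records, samples=("s1", "s2"), with_ds=True):
    """records: list of (chrom, pos, ref, alt, [genotype strings])."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n')
        if with_ds:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="d">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, cells in records:
            fmt = "GT:DS" if with_ds else "GT"
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n")


class TestLoadCohort:
    def test_identity_merge_of_shared_sites(self, tmp_path):
        recs = [
            ("1", 100, "A", "T", ["0/0:0", "0/1:1"]),
            ("1", 200, "C", "G", ["1/1:2", "0/1:1"]),
            ("2", 50, "G", "A", ["0/1:1", "0/0:0"]),
        ]
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        _write_simple_vcf(pa, recs)
        _write_simple_vcf(pb, recs)
        cohort = load_cohort([str(pa), str(pb)], ["A", "B"])
        assert cohort.n_variants == 3
        assert cohort.n_lines == 2
        np.testing.assert_array_equal(cohort.lines["A"].dosage, cohort.lines["B"].dosage)

    def test_union_marks_absent_sites_not_called(self, tmp_path):
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        _write_simple_vcf(pa, [("1", 100, "A", "T", ["0/1:1", "0/0:0"])])
        _write_simple_vcf(pb, [("1", 200, "C", "G", ["0/0:0", "0/0:0"])])
        cohort = load_cohort([str(pa), str(pb)], ["A", "B"])
        assert cohort.n_variants == 2
        # site 1:100 absent from B: not called there, but dosage 0 is a call
        assert not cohort.lines["B"].called[0]
        assert cohort.lines["B"].called[1]
        assert np.isnan(cohort.lines["B"].dosage[0]).all()

    def test_gt_only_vcf_heterozygote_is_dosage_one(self, tmp_path):
        p = tmp_path / "a.vcf"
        _write_simple_vcf(p, [("1", 100, "A", "T", ["0/1", "1/1"])], with_ds=False)
        cohort = load_cohort([str(p)], ["A"])
        np.testing.assert_array_equal(cohort.lines["A"].dosage[0], [1.0, 2.0])

    def test_multiallelic_record_rejected_with_site(self, tmp_path):
        p = tmp_path / "a.vcf"
        _write_simple_vcf(p, [("1", 100, "A", "T,G", ["0/1", "1/1"])], with_ds=False)
        with pytest.raises(ValueError, match="1:100"):
            load_cohort([str(p)], ["A"])

    def test_conflicting_ref_alleles_hard_error(self, tmp_path):
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        _write_simple_vcf(pa, [("1", 100, "A", "T", ["0/1", "0/0"])], with_ds=False)
        _write_simple_vcf(pb, [("1", 100, "C", "T", ["0/1", "0/0"])], with_ds=False)
        with pytest.raises(ValueError, match="conflicting REF"):
            load_cohort([str(pa), str(pb)], ["A", "B"])

    def test_missing_genotype_fails_fast_unless_imputing(self, tmp_path):
        p = tmp_path / "a.vcf"
        _write_simple_vcf(p, [("1", 100, "A", "T", ["./.", "0/1"])], with_ds=False)
        with pytest.raises(ValueError, match="missing genotype"):
            load_cohort([str(p)], ["A"])
        cfg = AnalysisConfig(impute_missing=True)
        cohort = load_cohort([str(p)], ["A"], config=cfg)
        np.testing.assert_array_equal(cohort.lines["A"].dosage[0], [1.0, 1.0])

    def test_merge_is_order_independent(self, tmp_path):
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        _write_simple_vcf(pa, [("1", 100, "A", "T", ["0/1:1", "0/0:0"])])
        _write_simple_vcf(pb, [("2", 10, "C", "G", ["1/1:2", "0/1:1"]), ("1", 300, "G", "C", ["0/0:0", "0/1:1"])])
        c1 = load_cohort([str(pa), str(pb)], ["A", "B"])
        c2 = load_cohort([str(pb), str(pa)], ["B", "A"])
        assert [v.variant_id for v in c1.variants] == [v.variant_id for v in c2.variants]
        for lid in ("A", "B"):
            np.testing.assert_array_equal(
                np.nan_to_num(c1.lines[lid].dosage, nan=-1),
                np.nan_to_num(c2.lines[lid].dosage, nan=-1),
            )


class TestSimulatorRoundTrip:
    def test_vcf_round_trip_reproduces_dosages_exactly(self, small_sim, tmp_path):
        from linevar.simulate import write_simulation

        paths = write_simulation(small_sim, tmp_path)
        vcfs = [str(paths[f"vcf_{l}"]) for l in small_sim.cohort.line_ids]
        cohort = load_cohort(vcfs, small_sim.cohort.line_ids)
        assert [v.variant_id for v in cohort.variants] == [
            v.variant_id for v in small_sim.cohort.variants
        ]
        for lid, line in small_sim.cohort.lines.items():
            got = cohort.lines[lid].dosage
            np.testing.assert_array_equal(np.isnan(got), np.isnan(line.dosage))
            np.testing.assert_array_equal(np.nan_to_num(got), np.nan_to_num(line.dosage))


class TestRepetitiveMask:
    def test_depth_above_three_times_coverage_excluded(self):
        dt = DepthTable(np.array([13.0, 12.0, 4.1]), 4.1)
        np.testing.assert_array_equal(repetitive_mask(dt), [True, False, False])

    def test_exactly_three_times_retained(self):
        dt = DepthTable(np.array([3 * 4.1]), 4.1)
        assert not repetitive_mask(dt)[0]

    def test_uniform_depth_nothing_excluded_and_idempotent(self):
        dt = DepthTable(np.full(5, 4.1), 4.1)
        m = repetitive_mask(dt)
        assert not m.any()
        np.testing.assert_array_equal(m, repetitive_mask(dt))

    def test_negative_depth_hard_error(self):
        with pytest.raises(ValueError):
            DepthTable(np.array([-1.0]), 4.1)


class TestWriteTable:
    def test_round_trip_identity(self, tmp_path):
        df = pd.DataFrame({"a": [1, 2, 3], "b": ["x", "y", "z"], "c": [0.125, 2.5, -3.0]})
        p = tmp_path / "t.tsv"
        write_table(df, p)
        back = read_table(p)
        pd.testing.assert_frame_equal(back, df)

    def test_empty_records_yield_header_only(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_table(pd.DataFrame(columns=["a", "b"]), p)
        back = read_table(p)
        assert list(back.columns) == ["a", "b"]
        assert back.empty

    def test_floats_survive_at_six_significant_digits(self, tmp_path):
        df = pd.DataFrame({"x": [1 / 3, 1e-7, 123456.789]})
        p = tmp_path / "t.tsv"
        write_table(df, p)
        back = read_table(p)
        np.testing.assert_allclose(back["x"], df["x"], rtol=1e-5)

    def test_seed_and_config_echoed_in_header(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_table(pd.DataFrame({"a": [1]}), p, AnalysisConfig(seed=99))
        header = p.read_text().splitlines()
        assert any("seed=99" in line for line in header if line.startswith("#"))

    def test_unwritable_destination_names_path(self, tmp_path):
        bad = tmp_path / "nope" / "t.tsv"
        with pytest.raises(OSError, match="nope"):
            write_table(pd.DataFrame({"a": [1]}), bad)


class TestRecombinationMap:
    def test_overlapping_windows_rejected(self):
        df = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [0, 500_000], "end": [1_000_000, 1_500_000],
             "rate": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="overlap"):
            RecombinationMap(df)
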