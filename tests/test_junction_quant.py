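"""Junction extraction, count-file dialects, and the cassette usage statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicequant.gene_models import CassetteEvent, JunctionKey
from splicequant.junction_quant import (
    JunctionCountTable,
    compute_usage,
    extract_junctions,
    normalize_depth,
    read_junction_table,
    summarize_samples,
    write_junction_table,
)
from splicequant.synthetic_data import SimConfig, simulate_junction_table, simulate_reads

from _oracles import make_record

EVENT = CassetteEvent(
    "4R",
    (JunctionKey("chr12", 17112299, 17122167), JunctionKey("chr12", 17108761, 17112207)),
    JunctionKey("chr12", 17108761, 17122167),
)


def table_for(x910, x1011, x911, sample="s"):
    return JunctionCountTable(
        sample,
        {
            JunctionKey("chr12", 17112299, 17122167): x910,
            JunctionKey("chr12", 17108761, 17112207): x1011,
            JunctionKey("chr12", 17108761, 17122167): x911,
        },
        library_size=x910 + x1011 + x911,
    )


class TestExtractJunctions:
    def test_single_skip_coordinates(self, sam_header):
        """30M 100N 45M at position 101 spans the junction (130, 231)."""
        rec = make_record(sam_header, "r1", 101, "30M100N45M")
        table = extract_junctions([rec])
        assert table.counts == {JunctionKey("chr12", 130, 231): 1}
        assert table.library_size == 1

    def test_two_skips_counted_independently(self, sam_header):
        rec = make_record(sam_header, "r1", 101, "20M50N93M60N25M")
        table = extract_junctions([rec])
        assert table.counts == {
            JunctionKey("chr12", 120, 171): 1,
            JunctionKey("chr12", 263, 324): 1,
        }

    def test_secondary_supplementary_unmapped_skipped(self, sam_header):
        recs = [
            make_record(sam_header, "sec", 101, "30M100N45M", flag=256),
            make_record(sam_header, "sup", 101, "30M100N45M", flag=2048),
            make_record(sam_header, "prim", 101, "75M"),
        ]
        unmapped = make_record(sam_header, "un", 101, "75M")
        unmapped.flag = 4
        table = extract_junctions(recs + [unmapped])
        assert table.counts == {} and table.library_size == 1

    def test_min_anchor_filters_short_overhangs(self, sam_header):
        rec = make_record(sam_header, "r1", 101, "5M100N70M")
        assert extract_junctions([rec], min_anchor=5).counts != {}
        assert extract_junctions([rec], min_anchor=6).counts == {}
        # library size still counts the record either way
        assert extract_junctions([rec], min_anchor=6).library_size == 1

    def test_deletion_does_not_create_junction(self, sam_header):
        rec = make_record(sam_header, "r1", 101, "30M5D45M")
        assert extract_junctions([rec]).counts == {}

    def test_empty_input(self):
        table = extract_junctions([])
        assert table.counts == {} and table.library_size == 0

    def test_matches_simulator_ledger_pure_exclusion(self, toy_model):
        cfg = SimConfig(
            model=toy_model,
            proportions={"inc": 0.0, "exc": 1.0},
            n_reads=1000,
            seed=7,
        )
        _, records, truth = simulate_reads(cfg)
        table = extract_junctions(records)
        assert table.counts == truth.junction_counts
        inc_junctions = toy_model.events[0].inclusion_junctions
        assert all(table.get(j) == 0 for j in inc_junctions)
        assert table.get(toy_model.events[0].exclusion_junction) > 0


class TestDialects:
    def test_plain_tsv_row(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("chr12\t17112299\t17122167\t+\t57\n")
        table = read_junction_table(p, "plain_tsv")
        assert table.get(JunctionKey("chr12", 17112299, 17122167)) == 57

    def test_star_sj_intron_shift(self, tmp_path):
        p = tmp_path / "SJ.out.tab"
        # intron [17112300, 17122166] -> exonic flanks (17112299, 17122167)
        p.write_text("chr12\t17112300\t17122166\t2\t2\t1\t57\t3\t40\n")
        table = read_junction_table(p, "star_sj")
        assert table.counts == {JunctionKey("chr12", 17112299, 17122167): 57}

    def test_jcounts_dialect(self, tmp_path):
        p = tmp_path / "x.jcounts"
        p.write_text(
            "PrimaryGene\tSecondaryGenes\tSite1_chr\tSite1_location\tSite1_strand"
            "\tSite2_chr\tSite2_location\tSite2_strand\tsample1\n"
            "MAPT\tNA\tchr12\t17112299\t-\tchr12\t17122167\t-\t57\n"
        )
        table = read_junction_table(p, "jcounts")
        assert table.get(JunctionKey("chr12", 17112299, 17122167)) == 57

    def test_descending_print_order_normalized(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("chr12\t17122167\t17112299\t-\t5\n")
        table = read_junction_table(p, "plain_tsv")
        assert table.get(JunctionKey("chr12", 17112299, 17122167)) == 5

    def test_round_trip(self, tmp_path):
        table = table_for(50, 60, 100)
        path = tmp_path / "out.tsv"
        write_junction_table(table, path)
        back = read_junction_table(path, "plain_tsv")
        assert back.counts == table.counts
        assert back.library_size == table.library_size  # sidecar honoured

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("x\n")
        with pytest.raises(ValueError, match="dialect"):
            read_junction_table(p, "nope")

    def test_non_integer_position_reports_line(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text("chr12\tabc\t17122167\t+\t5\n")
        with pytest.raises(ValueError, match=":1"):
            read_junction_table(p, "plain_tsv")


class TestNormalizeDepth:
    def test_per_million(self):
        table = table_for(50, 0, 0)
        out = normalize_depth(table, 10**6)
        assert out.normalized[JunctionKey("chr12", 17112299, 17122167)] == 50.0
        out2 = normalize_depth(table, 2 * 10**6)
        assert out2.normalized[JunctionKey("chr12", 17112299, 17122167)] == 25.0
        assert out2.counts == table.counts  # raw untouched

    def test_invalid_library_size(self):
        with pytest.raises(ValueError):
            normalize_depth(table_for(1, 1, 1), 0)

    def test_usage_unchanged_by_normalization(self):
        table = table_for(41, 37, 202)
        before = compute_usage(table, EVENT).usage_percent
        after = compute_usage(normalize_depth(table, 123456), EVENT).usage_percent
        assert after == pytest.approx(before)


class TestComputeUsage:
    def test_worked_formula(self):
        r = compute_usage(table_for(50, 50, 100), EVENT)
        assert r.usage_percent == 50.0
        assert r.inclusion_fraction_hat == pytest.approx(1 / 3)
        assert r.defined

    def test_pure_exclusion_is_zero(self):
        r = compute_usage(table_for(0, 0, 200), EVENT)
        assert r.usage_percent == 0.0 and r.inclusion_fraction_hat == 0.0

    def test_zero_exclusion_undefined(self):
        r = compute_usage(table_for(50, 50, 0), EVENT)
        assert not r.defined and r.usage_percent is None

    def test_absent_junctions_count_as_zero(self):
        table = JunctionCountTable("s", {}, 0)
        r = compute_usage(table, EVENT)
        assert not r.defined and r.x_inclusion == (0.0, 0.0)

    @given(
        x910=st.integers(0, 10**6),
        x1011=st.integers(0, 10**6),
        x911=st.integers(1, 10**6),
        c=st.integers(1, 1000),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_identity(self, x910, x1011, x911, c):
        """usage is invariant to count scaling; usage/100 == f_hat/(1-f_hat)."""
        base = compute_usage(table_for(x910, x1011, x911), EVENT)
        scaled = compute_usage(
            table_for(c * x910, c * x1011, c * x911), EVENT
        )
        assert scaled.usage_percent == pytest.approx(base.usage_percent)
        f = base.inclusion_fraction_hat
        assert base.usage_percent / 100 == pytest.approx(f / (1 - f))

    def test_monotone_in_inclusion_counts(self):
        low = compute_usage(table_for(50, 50, 100), EVENT).usage_percent
        hi1 = compute_usage(table_for(51, 50, 100), EVENT).usage_percent
        hi2 = compute_usage(table_for(50, 51, 100), EVENT).usage_percent
        assert hi1 > low and hi2 > low


class TestSummarize:
    def test_mean_sd_n(self):
        results = [
            compute_usage(table_for(x, x, 100), EVENT) for x in (10, 20, 30)
        ]
        s = summarize_samples(results)
        assert (s.mean, s.sd, s.n) == (20.0, 10.0, 3)

    def test_single_sample_sd_flagged(self):
        s = summarize_samples([compute_usage(table_for(17, 17, 100), EVENT)])
        assert s.mean == 17.0 and s.sd is None and s.n == 1

    def test_undefined_excluded_and_counted(self):
        results = [
            compute_usage(table_for(10, 10, 100), EVENT),
            compute_usage(table_for(10, 10, 0), EVENT),
        ]
        s = summarize_samples(results)
        assert s.n == 1 and s.n_undefined == 1

    def test_all_undefined_raises(self):
        with pytest.raises(ValueError):
            summarize_samples([compute_usage(table_for(1, 1, 0), EVENT)])

    def test_replicates_recover_study_scale_ratio(self, toy_model):
        """Three simulated replicates at f = 0.148 average near 17.37%."""
        results = []
        for seed in (11, 12, 13):
            cfg = SimConfig(model=toy_model, seed=seed, n_reads=10**5)
            table, _ = simulate_junction_table(cfg)
            results.append(compute_usage(table, toy_model.events[0]))
        s = summarize_samples(results)
        assert s.n == 3
        assert s.mean == pytest.approx(17.37, abs=1.5)


class TestEstimatorConsistency:
    @pytest.mark.parametrize("f", [0.1, 0.3, 0.5])
    def test_inclusion_fraction_recovered(self, toy_model, f):
        """Mean |f_hat - f| < 0.01 at 1e5 reads over 20 seeds."""
        errors = []
        for seed in range(20):
            cfg = SimConfig(
                model=toy_model,
                proportions={"inc": f, "exc": 1 - f},
                n_reads=10**5,
                seed=seed,
            )
            table, _ = simulate_junction_table(cfg)
            r = compute_usage(table, toy_model.events[0])
            errors.append(abs(r.inclusion_fraction_hat - f))
        assert np.mean(errors) < 0.01
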