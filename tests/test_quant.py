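"""Coverage extraction, median/normalization quantification, derived stats."""

import math

import numpy as np
import pytest

from mulsec import (
    CoverageProfile,
    PoolQuant,
    apply_cutoff,
    confusion_stats,
    coverage_from_alignments,
    enrichment,
    enrichment_table,
    fold_killing,
    median_coverage,
    normalize_pool,
    pool_summary,
    quantify_pool,
    simulate_reads,
    soluble_fraction,
)
from mulsec.errors import DropoutError, EmptyPoolError, MulsecError, UnknownReferenceError
from mulsec.quant import read_median_tsv, read_pileup_tsv


def _write_sam(path, refs, records):
    """records: (name, flag, ref, pos0, cigar, seq)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in refs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for name, flag, ref, pos, cigar, seq in records:
            fh.write(
                f"{name}\t{flag}\t{ref}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )


class TestCoverage:
    def test_zero_alignments_all_zero(self, tmp_path):
        sam = tmp_path / "empty.sam"
        _write_sam(sam, {"g1": 100}, [])
        profiles = coverage_from_alignments(sam)
        assert profiles["g1"].counts.sum() == 0
        assert profiles["g1"].length == 100

    def test_single_perfect_alignment_interval(self, tmp_path):
        sam = tmp_path / "one.sam"
        _write_sam(sam, {"g1": 100}, [("r1", 0, "g1", 10, "50M", "A" * 50)])
        counts = coverage_from_alignments(sam)["g1"].counts
        assert (counts[10:60] == 1).all()
        assert counts[:10].sum() == 0 and counts[60:].sum() == 0

    def test_deletions_and_clips_do_not_count(self, tmp_path):
        sam = tmp_path / "cigar.sam"
        _write_sam(
            sam, {"g1": 100},
            [("r1", 0, "g1", 0, "5S10M5D10M", "A" * 25)],
        )
        counts = coverage_from_alignments(sam)["g1"].counts
        assert (counts[0:10] == 1).all()
        assert (counts[10:15] == 0).all()  # deletion
        assert (counts[15:25] == 1).all()

    def test_secondary_records_excluded_by_default(self, tmp_path):
        sam = tmp_path / "sec.sam"
        _write_sam(
            sam, {"g1": 100},
            [("r1", 0, "g1", 0, "10M", "A" * 10), ("r1", 256, "g1", 50, "10M", "A" * 10)],
        )
        counts = coverage_from_alignments(sam)["g1"].counts
        assert counts[50:60].sum() == 0

    def test_unknown_reference_raises(self, tmp_path):
        sam = tmp_path / "bad.sam"
        _write_sam(sam, {"g1": 100}, [("r1", 0, "g1", 0, "10M", "A" * 10)])
        with pytest.raises(UnknownReferenceError):
            coverage_from_alignments(sam, references={"other": 100})

    def test_simulated_reads_match_interval_oracle(self, tmp_path):
        rng = np.random.default_rng(0)
        refs = {
            "g1": "".join(rng.choice(list("ACGT"), size=300)),
            "g2": "".join(rng.choice(list("ACGT"), size=400)),
        }
        sam = tmp_path / "sim.sam"
        simulate_reads(refs, {"g1": 0.4, "g2": 0.6}, 1000, 50, seed=1, sam_path=sam)
        profiles = coverage_from_alignments(sam)
        # naive oracle: accumulate [pos, pos+50) intervals straight from the text
        oracle = {g: np.zeros(len(s), dtype=int) for g, s in refs.items()}
        for line in open(sam):
            if line.startswith("@"):
                continue
            f = line.split("\t")
            pos = int(f[3]) - 1
            oracle[f[2]][pos : pos + 50] += 1
        for g in refs:
            assert (profiles[g].counts == oracle[g]).all()


class TestMedianAndNormalize:
    def test_uniform_coverage(self):
        assert median_coverage(CoverageProfile("g", np.full(100, 7))) == 7.0

    def test_small_example(self):
        assert median_coverage(CoverageProfile("g", [0, 0, 5, 7, 9])) == 5.0

    def test_even_length_mean_of_central_pair(self):
        assert median_coverage(CoverageProfile("g", [1, 2, 3, 10])) == 2.5

    def test_matches_sort_oracle_on_random_profiles(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            counts = rng.integers(0, 50, size=int(rng.integers(1, 40)))
            srt = sorted(counts)
            n = len(srt)
            expected = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
            assert median_coverage(CoverageProfile("g", counts)) == expected

    def test_nonzero_only_flag(self):
        assert median_coverage(CoverageProfile("g", [0, 0, 4, 6]), nonzero_only=True) == 5.0

    def test_single_gene_normalizes_to_one(self):
        assert normalize_pool({"g": 42.0}) == {"g": 1.0}

    def test_published_median_ratio(self):
        """BLVRB:HAMI = 3197:1131 must normalize to the printed 2.82 ratio."""
        f = normalize_pool({"BLVRB": 3197.0, "HAMI": 1131.0})
        assert f["BLVRB"] / f["HAMI"] == pytest.approx(2.8267, abs=1e-3)
        assert round(f["BLVRB"] / f["HAMI"], 2) == 2.83

    def test_fractions_sum_to_one_random_pools(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            medians = {f"g{i}": float(rng.integers(0, 500)) for i in range(20)}
            if sum(medians.values()) == 0:
                continue
            f = normalize_pool(medians)
            assert abs(sum(f.values()) - 1.0) < 1e-9
            total = sum(medians.values())
            for g in medians:
                assert f[g] == medians[g] / total

    def test_all_zero_pool_rejected(self):
        with pytest.raises(EmptyPoolError):
            normalize_pool({"g": 0.0})


class TestCutoffEnrichment:
    def test_boundary_is_inclusive(self):
        assert apply_cutoff({"a": 0.0005, "b": 0.00049}) == {"a"}

    def test_zero_threshold_keeps_positive(self):
        assert apply_cutoff({"a": 0.1, "b": 0.0}, threshold=1e-12) == {"a"}

    def test_random_pools_match_brute_filter(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            fr = {f"g{i}": float(rng.random()) / 100 for i in range(30)}
            t = float(rng.random()) / 100
            assert apply_cutoff(fr, t) == {g for g, v in fr.items() if v >= t}

    def test_equal_fractions_give_unity(self):
        assert enrichment(0.1, 0.1) == 1.0

    def test_published_blvrb_enrichment(self):
        assert enrichment(0.34, 0.21) == pytest.approx(1.6, abs=0.02)

    def test_published_ssea_enrichment(self):
        assert enrichment(0.073, 0.002) == pytest.approx(36.5, abs=0.1)

    def test_dropout_raises(self):
        with pytest.raises(DropoutError):
            enrichment(0.1, 0.0)

    def test_enrichment_table_marks_dropouts(self):
        df = enrichment_table({"a": 0.2, "b": 0.1}, {"a": 0.1, "b": 0.0})
        by_gene = df.set_index("gene_id")
        assert by_gene.loc["a", "fold"] == pytest.approx(2.0)
        assert by_gene.loc["b", "status"] == "dropout"
        assert math.isnan(by_gene.loc["b", "fold"])


class TestDerivedStats:
    def test_identical_sets_are_100_0(self):
        assert confusion_stats({"a", "b"}, {"a", "b"}) == {"tp_rate": 100.0, "fn_rate": 0.0}

    def test_published_text_mining_rates(self):
        pred = {f"g{i}" for i in range(43)} | {f"x{i}" for i in range(15)}
        obs = {f"g{i}" for i in range(52)}
        rates = confusion_stats(pred, obs)
        assert rates["tp_rate"] == pytest.approx(82.69, abs=0.01)
        assert round(rates["tp_rate"]) == 83
        assert round(rates["fn_rate"]) == 17

    def test_empty_observed_rejected(self):
        with pytest.raises(MulsecError):
            confusion_stats({"a"}, set())

    def test_soluble_fraction_examples(self):
        assert soluble_fraction(1.0, 1.0) == 0.5
        assert soluble_fraction(0.0, 2.0) == 0.0
        with pytest.raises(MulsecError):
            soluble_fraction(0.0, 0.0)

    def test_fold_killing_examples(self):
        assert fold_killing(100, 100) == 1.0
        assert fold_killing(400, 2) == 200.0
        assert fold_killing(400, 0) == math.inf  # censored: report as "> 400"
        with pytest.raises(MulsecError):
            fold_killing(0, 10)


class TestPoolSummary:
    def test_single_gene_pool(self):
        q = PoolQuant.from_medians("p", 5.0, {"g": 10.0})
        row = pool_summary([q]).iloc[0]
        assert row["n_detected"] == 1
        assert row["n_passing"] == 1
        assert row["median_fraction_passing"] == 1.0

    def test_constructed_95_gene_pool_passes_75(self):
        medians = {f"g{i}": 100.0 for i in range(75)}
        medians.update({f"low{i}": 0.003 for i in range(20)})  # far below 0.05%
        q = PoolQuant.from_medians("p", 5.0, medians)
        assert len(q.medians) == 95
        assert pool_summary([q]).iloc[0]["n_passing"] == 75

    def test_outliers_match_brute_iqr(self):
        rng = np.random.default_rng(4)
        medians = {f"g{i}": float(rng.integers(50, 100)) for i in range(40)}
        medians["hot"] = 5000.0
        q = PoolQuant.from_medians("p", 5.0, medians)
        row = pool_summary([q]).iloc[0]
        fr = [q.fractions[g] for g in sorted(q.passing)]
        q1, q3 = np.percentile(fr, [25, 75])
        iqr = q3 - q1
        brute = {
            g for g in sorted(q.passing)
            if q.fractions[g] < q1 - 1.5 * iqr or q.fractions[g] > q3 + 1.5 * iqr
        }
        assert set(row["outliers"].split(",")) - {""} == brute
        assert "hot" in brute


class TestInvariantsAndIngestion:
    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        profiles = {
            f"g{i}": CoverageProfile(f"g{i}", rng.integers(0, 100, size=50))
            for i in range(10)
        }
        scaled = {g: CoverageProfile(g, p.counts * 7) for g, p in profiles.items()}
        qa = quantify_pool(profiles, "a", 5.0)
        qb = quantify_pool(scaled, "b", 5.0)
        for g in profiles:
            assert qa.fractions[g] == pytest.approx(qb.fractions[g], abs=1e-12)
        assert qa.passing == qb.passing

    def test_pipeline_determinism(self, tmp_path):
        rng = np.random.default_rng(6)
        refs = {"g1": "".join(rng.choice(list("ACGT"), size=300))}
        sam = tmp_path / "d.sam"
        simulate_reads(refs, {"g1": 1.0}, 500, 50, seed=7, sam_path=sam)
        a = quantify_pool(coverage_from_alignments(sam), "p", 5.0)
        b = quantify_pool(coverage_from_alignments(sam), "p", 5.0)
        assert a.fractions == b.fractions and a.medians == b.medians

    def test_pileup_and_median_tsv_readers(self, tmp_path):
        pileup = tmp_path / "cov.pileup.tsv"
        pileup.write_text("g1\t0\t3\ng1\t1\t5\ng1\t2\t5\ng2\t0\t9\n")
        profiles = read_pileup_tsv(pileup)
        assert list(profiles["g1"].counts) == [3, 5, 5]
        assert median_coverage(profiles["g2"]) == 9.0
        med = tmp_path / "medians.tsv"
        med.write_text("g1\t5\ng2\t9\n")
        assert read_median_tsv(med) == {"g1": 5.0, "g2": 9.0}
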