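import numpy as np
import pytest

from epiallele.align import align_bisulfite, revcomp
from epiallele.calling import (
    call_read_pattern,
    call_reads,
    call_sample,
    classify_read,
    demultiplex,
    export_pattern_matrix,
    filter_reads,
    group_reads_by_locus,
    summarize_locus,
)
from epiallele.simulate import SampleSpec, bisulfite_convert, simulate_cohort


def convert_clean(locus, methylated: bool) -> str:
    """Perfectly converted read from a coherent allele (no noise)."""
    rng = np.random.default_rng(0)
    return bisulfite_convert(
        locus.reference,
        np.full(locus.n_cpgs, methylated, bool),
        1.0,
        0.0,
        rng,
        locus=locus,
    )


class TestDemultiplex:
    MIDS = {"ACGTAC": "s1", "TGCATG": "s2", "CATGCA": "s3"}

    def test_exact_prefix_assigned_and_trimmed(self):
        per_sample, unassigned = demultiplex(
            [("r1", "ACGTAC" + "TTTT")], self.MIDS, max_mismatches=1
        )
        assert per_sample["s1"] == [("r1", "TTTT")]
        assert not unassigned

    def test_two_mismatches_unassigned(self):
        # ACGTAC with 2 substitutions: distance 2 from s1, >2 from others
        per_sample, unassigned = demultiplex(
            [("r1", "AAGAAC" + "TTTT")], self.MIDS, max_mismatches=1
        )
        assert unassigned == [("r1", "AAGAACTTTT")]
        assert all(not v for v in per_sample.values())

    def test_ambiguous_mid_table_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            demultiplex([], {"AAAA": "a", "AATA": "b"}, max_mismatches=1)

    def test_unequal_mid_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            demultiplex([], {"AAAA": "a", "TTTTT": "b"})

    def test_planted_single_mismatches_fully_recovered(self, rng):
        """1000 reads, each with one planted MID mismatch, all assigned."""
        mids = list(self.MIDS)
        reads = []
        truth = []
        bases = "ACGT"
        for i in range(1000):
            mid = mids[rng.integers(len(mids))]
            pos = rng.integers(len(mid))
            sub = bases[(bases.index(mid[pos]) + 1 + rng.integers(3)) % 4]
            mutated = mid[:pos] + sub + mid[pos + 1:]
            payload = "".join(np.random.default_rng(i).choice(list(bases), 20))
            reads.append((f"r{i}", mutated + payload))
            truth.append(self.MIDS[mid])
        per_sample, unassigned = demultiplex(reads, self.MIDS, max_mismatches=1)
        assert not unassigned
        assigned = {rid: s for s, rs in per_sample.items() for rid, _ in rs}
        assert all(assigned[f"r{i}"] == truth[i] for i in range(1000))


class TestCallReadPattern:
    def test_fully_converted_unmethylated_read(self, tiny_locus):
        read = convert_clean(tiny_locus, methylated=False)
        pattern = call_read_pattern(align_bisulfite(read, tiny_locus), tiny_locus)
        assert pattern.calls == "U" * tiny_locus.n_cpgs
        assert pattern.conversion_rate_read == 1.0
        assert pattern.aligned_fraction == 1.0

    def test_fully_methylated_read(self, tiny_locus):
        read = convert_clean(tiny_locus, methylated=True)
        pattern = call_read_pattern(align_bisulfite(read, tiny_locus), tiny_locus)
        assert pattern.calls == "M" * tiny_locus.n_cpgs
        assert pattern.conversion_rate_read == 1.0

    def test_planted_conversion_failures_counted(self, panel_by_name):
        """Conversion failures at 3 of 15 non-CpG Cs give rate 12/15."""
        locus = panel_by_name["DDX4"]
        read = list(convert_clean(locus, methylated=False))
        for p in locus.non_cpg_c_positions[:3]:
            read[p] = "C"  # unconverted cytosine
        pattern = call_read_pattern(
            align_bisulfite("".join(read), locus), locus
        )
        n = len(locus.non_cpg_c_positions)
        assert pattern.conversion_rate_read == pytest.approx((n - 3) / n)

    def test_orientation_symmetry(self, panel_by_name, rng):
        """Reverse-complemented input reads yield identical patterns."""
        locus = panel_by_name["MEST"]
        for methylated in (False, True):
            allele = np.full(locus.n_cpgs, methylated, bool)
            read = bisulfite_convert(
                locus.reference, allele, 0.99, 0.005, rng, locus=locus
            )
            p_fwd = call_read_pattern(align_bisulfite(read, locus), locus)
            p_rev = call_read_pattern(align_bisulfite(revcomp(read), locus), locus)
            assert p_rev.calls == p_fwd.calls
            assert p_rev.conversion_rate_read == p_fwd.conversion_rate_read
            assert p_rev.orientation == "reverse-complement"

    def test_calls_conservation(self, panel_by_name, rng):
        """#M + #U + #N equals the number of locus CpGs for every read."""
        locus = panel_by_name["H19"]
        spec = SampleSpec(
            sample_id="x", fraction="blood", n_reads_per_locus=100,
            conversion_rate=0.98, seq_error_rate=0.01,
        )
        reads, _, _ = simulate_cohort([locus], [spec], 3)
        for pattern in call_reads(reads["x"].reads["H19"], locus):
            assert len(pattern.calls) == locus.n_cpgs
            counts = {c: pattern.calls.count(c) for c in "MUN"}
            assert sum(counts.values()) == locus.n_cpgs


class TestFilterReads:
    def test_thresholds(self, tiny_locus):
        read = convert_clean(tiny_locus, methylated=False)
        pattern = call_read_pattern(align_bisulfite(read, tiny_locus), tiny_locus)
        passing, report = filter_reads([pattern], min_conversion=0.95)
        assert passing == [pattern] and pattern.pass_qc
        # plant conversion failures to push the rate to 4/6 < 0.95
        low = list(read)
        for p in tiny_locus.non_cpg_c_positions[:2]:
            low[p] = "C"
        bad = call_read_pattern(align_bisulfite("".join(low), tiny_locus), tiny_locus)
        passing, report = filter_reads([bad], min_conversion=0.95)
        assert not passing and not bad.pass_qc and bad.fail_reason == "conversion"
        assert report["fail_conversion"] == 1

    def test_planted_low_conversion_reads_removed(self, panel_by_name, rng):
        """The filter removes exactly the planted low-conversion read ids."""
        locus = panel_by_name["FGFR3"]
        reads = []
        planted_bad = set()
        for i in range(200):
            rid = f"r{i}"
            if i % 20 == 0:  # 5% with conversion 0.5
                seq = bisulfite_convert(
                    locus.reference, np.zeros(locus.n_cpgs, bool), 0.5, 0.0,
                    np.random.default_rng(1000 + i), locus=locus,
                )
                planted_bad.add(rid)
            else:
                seq = convert_clean(locus, methylated=False)
            reads.append((rid, seq))
        patterns = call_reads(reads, locus)
        passing, report = filter_reads(patterns, min_conversion=0.9)
        failed_ids = {p.read_id for p in patterns if not p.pass_qc}
        assert failed_ids == planted_bad
        assert report["n_pass"] == 200 - len(planted_bad)


class TestSummarize:
    def make_patterns(self, tiny_locus, m_reads, u_reads):
        patterns = []
        for i in range(m_reads):
            read = convert_clean(tiny_locus, methylated=True)
            p = call_read_pattern(align_bisulfite(read, tiny_locus), tiny_locus)
            p.read_id = f"m{i}"
            patterns.append(p)
        for i in range(u_reads):
            read = convert_clean(tiny_locus, methylated=False)
            p = call_read_pattern(align_bisulfite(read, tiny_locus), tiny_locus)
            p.read_id = f"u{i}"
            patterns.append(p)
        return filter_reads(patterns)[0]

    def test_mixture_arithmetic(self, tiny_locus):
        """4 fully methylated + 6 fully unmethylated reads: mean 40%."""
        summary = summarize_locus(
            self.make_patterns(tiny_locus, 4, 6), sample_id="s"
        )
        assert summary.mean_methylation == pytest.approx(40.0)
        assert summary.p_unmeth == pytest.approx(0.6)
        assert summary.p_meth == pytest.approx(0.4)
        assert summary.p_mosaic == 0.0
        assert summary.p_unmeth + summary.p_meth + summary.p_mosaic == pytest.approx(
            1.0, abs=1e-9
        )

    def test_all_methylated(self, tiny_locus):
        summary = summarize_locus(self.make_patterns(tiny_locus, 10, 0), "s")
        assert summary.mean_methylation == 100.0
        assert summary.p_meth == 1.0

    def test_minor_call_threshold(self):
        """1 M among 12 calls is still an unmethylated read (1/12 <= 0.1)."""
        from epiallele.calling import ReadPattern

        p = ReadPattern("r", "L", "forward", "M" + "U" * 11, 1.0, 1.0, True)
        assert classify_read(p, 0.1) == "unmeth"
        p2 = ReadPattern("r", "L", "forward", "MM" + "U" * 10, 1.0, 1.0, True)
        assert classify_read(p2, 0.1) == "mosaic"

    def test_zero_passing_reads_is_missing(self):
        assert summarize_locus([], "s", "L") is None


class TestPatternMatrix:
    def test_matrix_layout_and_order(self, tiny_locus, tmp_path):
        patterns = TestSummarize().make_patterns(tiny_locus, 2, 3)
        path = tmp_path / "matrix.tsv"
        export_pattern_matrix(patterns, path, tiny_locus)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        assert header[0] == "read_id"
        # columns labeled with 1-based CpG positions
        assert header[1:] == [f"CpG_{p + 1}" for p in tiny_locus.cpg_positions]
        assert len(lines) == 1 + 5
        # descending M fraction: methylated reads first
        first_rows = [line.split("\t")[0] for line in lines[1:3]]
        assert set(first_rows) == {"m0", "m1"}
        # row M counts match the per-read calls
        for line in lines[1:]:
            fields = line.split("\t")
            pattern = next(p for p in patterns if p.read_id == fields[0])
            assert fields[1:] == list(pattern.calls)

    def test_empty_pattern_list_warns(self, tiny_locus, tmp_path):
        path = tmp_path / "empty.tsv"
        with pytest.warns(UserWarning, match="header-only"):
            export_pattern_matrix([], path, tiny_locus)
        assert path.read_text().count("\n") == 1


def test_end_to_end_mean_methylation_recovery(panel):
    """Called per-locus means track the generator's analytic expectation.

    Deterministic-compartment loci (germ markers, XIST in 46,XY) are checked
    at 500 reads; imprinted loci draw somatic alleles Bernoulli(0.5), so the
    2-point check needs the allele-sampling noise suppressed (5000 reads,
    SE ~0.7 pp).
    """
    from epiallele.simulate import expected_mean_methylation

    cases = [
        # pure soma at 500 reads: germ markers and XIST are deterministic,
        # only conversion/error noise remains (~0.6 pp)
        (0.0, 500, ("FGFR3", "DDX4", "RHOXF1", "XIST")),
        # mixtures and imprinted loci draw alleles at random; 5000 reads
        # brings the sampling SE to ~0.7 pp
        (0.3, 5000, None),
    ]
    for f, n_reads, names in cases:
        spec = SampleSpec(
            sample_id="s", group="KS", fraction="SN", karyotype="46,XY",
            germ_fraction=f, n_reads_per_locus=n_reads,
        )
        loci = [l for l in panel if names is None or l.name in names]
        reads, _, _ = simulate_cohort(loci, [spec], 21)
        summaries, _, _ = call_sample(reads["s"].reads, loci, "s")
        assert len(summaries) == len(loci)
        for s in summaries:
            locus = next(l for l in loci if l.name == s.locus)
            expected = expected_mean_methylation(
                locus.imprint_class, "46,XY", f
            )
            assert s.mean_methylation == pytest.approx(expected, abs=2.0), s.locus


def test_group_reads_by_locus():
    reads = [("s|H19|00001", "AC"), ("s|XIST|00002", "GT"), ("weird", "AA")]
    grouped = group_reads_by_locus(reads, ["H19", "XIST"])
    assert [r[0] for r in grouped["H19"]] == ["s|H19|00001"]
    assert [r[0] for r in grouped["XIST"]] == ["s|XIST|00002"]
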