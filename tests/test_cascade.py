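"""Filter cascade: boundary semantics, matching rules, audit invariants."""

import itertools

import numpy as np
import pytest

from cnvtriage.cascade import (
    CnvCall,
    CnvType,
    ControlCohort,
    FilterConfig,
    GeneModel,
    GeneSet,
    PopCnvType,
    PopulationCnvRecord,
    PopulationDb,
    ReviewDecision,
    SampleQc,
    Verdict,
    control_frequency,
    filter_dgv,
    filter_gene_content,
    filter_markers,
    filter_quality,
    qc_sample,
    run_cascade,
    screen_samples,
)
from cnvtriage.intervals import GenomicInterval, overlaps


def call(chrom="1", start=1000, end=2000, cnv_type=CnvType.DEL, lbf=50.0,
         n_markers=10, sample="f1"):
    return CnvCall(sample, GenomicInterval(chrom, start, end), cnv_type,
                   lbf, n_markers)


PERMISSIVE = GeneSet([GeneModel("G", GenomicInterval("1", 1, 9_999_999), True)])


class TestSampleQc:
    def test_below_threshold_fails(self):
        assert not qc_sample(SampleQc("s", 0.949))

    def test_exact_threshold_passes(self):
        # exclusion is "<95%", so exactly 95% is usable
        assert qc_sample(SampleQc("s", 0.95))

    def test_cohort_screen_with_planted_failures(self):
        rng = np.random.default_rng(0)
        qc = [SampleQc(f"s{i}", round(float(rng.uniform(0.955, 0.999)), 4))
              for i in range(33)]
        qc += [SampleQc("bad1", 0.93), SampleQc("bad2", 0.9499)]
        assert len(screen_samples(qc)) == 33


class TestQualityAndMarkers:
    def test_lbf_boundary(self):
        assert not filter_quality(call(lbf=29.99))
        assert filter_quality(call(lbf=30.0))

    def test_marker_boundary(self):
        assert not filter_markers(call(n_markers=2))
        assert filter_markers(call(n_markers=3))

    def test_uniform_lbf_retention_matches_recount(self):
        rng = np.random.default_rng(1)
        lbfs = rng.uniform(0, 60, size=1000)
        kept = sum(filter_quality(call(lbf=float(x))) for x in lbfs)
        assert kept == int((lbfs >= 30).sum())


class TestControlFrequency:
    def test_single_carrier_in_1307(self):
        target = call()
        cohort = ControlCohort(1307, [call(sample="c1")])
        freq = control_frequency(target, cohort)
        assert freq == 1 / 1307
        assert round(freq, 4) == 0.0008

    def test_no_match_is_zero(self):
        cohort = ControlCohort(100, [call(chrom="2", sample="c1")])
        assert control_frequency(call(), cohort) == 0.0

    def test_planted_matches_counted_per_individual(self):
        # 7 carriers of 50, one carrying two matching calls: frequency
        # counts individuals, not calls
        carriers = [call(sample=f"c{i}") for i in range(7)]
        carriers.append(call(start=1010, end=2010, sample="c0"))
        cohort = ControlCohort(50, carriers)
        assert control_frequency(call(), cohort) == 7 / 50

    def test_type_mismatch_not_a_match(self):
        cohort = ControlCohort(10, [call(cnv_type=CnvType.DUP, sample="c")])
        assert control_frequency(call(cnv_type=CnvType.DEL), cohort) == 0.0

    def test_reciprocal_overlap_rule(self):
        # shifted by 60% of length: reciprocal overlap 0.4 < 0.5 -> no match
        cohort = ControlCohort(10, [call(start=1601, end=2601, sample="c")])
        assert control_frequency(call(), cohort) == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            ControlCohort(0, [])


class TestGeneContent:
    def test_one_bp_coding_overlap_retains(self):
        genes = GeneSet([GeneModel("NEURO1", GenomicInterval("1", 2000, 3000),
                                   True)])
        keep, symbols = filter_gene_content(call(end=2000), genes)
        assert keep and symbols == ["NEURO1"]

    def test_gene_desert_excluded(self):
        genes = GeneSet([GeneModel("NEURO1", GenomicInterval("2", 1, 100), True)])
        keep, symbols = filter_gene_content(call(), genes)
        assert not keep and symbols == []

    def test_non_cns_gene_does_not_retain(self):
        genes = GeneSet([GeneModel("OTHER", GenomicInterval("1", 1000, 2000),
                                   False)])
        keep, _ = filter_gene_content(call(), genes)
        assert not keep

    def test_random_calls_match_per_base_oracle(self):
        rng = np.random.default_rng(2)
        genes = []
        for i in range(100):
            s = int(rng.integers(1, 90_000))
            genes.append(GeneModel(f"G{i}",
                                   GenomicInterval("1", s, s + int(rng.integers(10, 500))),
                                   bool(i < 30)))
        gs = GeneSet(genes)
        for _ in range(200):
            s = int(rng.integers(1, 90_000))
            c = call(start=s, end=s + int(rng.integers(10, 2000)))
            keep, symbols = filter_gene_content(c, gs)
            oracle = sorted(
                g.symbol for g in genes
                if g.cns_flag and overlaps(c.interval, g.coding_span)
            )
            assert symbols == oracle
            assert keep == bool(oracle)


class TestPopulationDb:
    @staticmethod
    def containing_records(n, cnv_type=PopCnvType.DEL):
        return [PopulationCnvRecord(GenomicInterval("1", 900, 2100),
                                    cnv_type, f"r{i}") for i in range(n)]

    def test_five_full_overlaps_excludes(self):
        keep, n = filter_dgv(call(), PopulationDb(self.containing_records(5)))
        assert not keep and n == 5

    def test_four_full_overlaps_keeps(self):
        keep, n = filter_dgv(call(), PopulationDb(self.containing_records(4)))
        assert keep and n == 4

    def test_partial_overlap_not_counted(self):
        db = PopulationDb([PopulationCnvRecord(
            GenomicInterval("1", 1500, 3000), PopCnvType.DEL, "r")] * 6)
        keep, n = filter_dgv(call(), db)
        assert keep and n == 0

    def test_mixed_type_compatible_with_both(self):
        db = PopulationDb(self.containing_records(5, PopCnvType.MIXED))
        assert not filter_dgv(call(cnv_type=CnvType.DEL), db)[0]
        assert not filter_dgv(call(cnv_type=CnvType.DUP), db)[0]

    def test_type_matching_can_be_disabled(self):
        db = PopulationDb(self.containing_records(5, PopCnvType.DUP))
        keep_matched, n_matched = filter_dgv(call(cnv_type=CnvType.DEL), db)
        keep_any, n_any = filter_dgv(
            call(cnv_type=CnvType.DEL), db, type_matched=False
        )
        assert keep_matched and n_matched == 0
        assert not keep_any and n_any == 5

    def test_random_counts_match_containment_oracle(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(500):
            s = int(rng.integers(1, 9000))
            records.append(PopulationCnvRecord(
                GenomicInterval("1", s, s + int(rng.integers(10, 3000))),
                PopCnvType.DEL, f"r{i}"))
        db = PopulationDb(records)
        from cnvtriage.intervals import contains
        for _ in range(50):
            s = int(rng.integers(1, 9000))
            c = call(start=s, end=s + int(rng.integers(10, 2000)))
            _, n = filter_dgv(c, db)
            oracle = sum(1 for r in records if contains(r.interval, c.interval))
            assert n == oracle


class TestReviewGate:
    def setup_method(self):
        self.cohort = ControlCohort(100, [])
        self.db = PopulationDb([])

    def test_no_decisions_is_identity(self):
        calls = [call(sample=f"s{i}") for i in range(5)]
        retained, _ = run_cascade(calls, self.cohort, self.db, PERMISSIVE)
        assert retained == calls

    def test_exclude_decision_fails_criterion_iv(self):
        c = call()
        decision = ReviewDecision(c.sample_id, c.interval, "exclude")
        retained, traces = run_cascade(
            [c], self.cohort, self.db, PERMISSIVE, decisions=[decision]
        )
        assert retained == []
        assert traces[0].verdicts["IV"] is Verdict.FAIL
        assert traces[0].verdicts["V"] is Verdict.NOT_EVALUATED

    def test_rebreak_into_flagged_gene_rescues_call(self):
        genes = GeneSet([GeneModel("BRAIN1", GenomicInterval("1", 5000, 6000),
                                   True)])
        c = call()  # 1000-2000: no gene overlap on the original interval
        widened = GenomicInterval("1", 1000, 5500)
        decision = ReviewDecision(c.sample_id, c.interval, "rebreak",
                                  new_interval=widened)
        # without the decision the call dies at criterion V
        assert run_cascade([c], self.cohort, self.db, genes)[0] == []
        retained, traces = run_cascade(
            [c], self.cohort, self.db, genes, decisions=[decision]
        )
        assert len(retained) == 1
        assert retained[0].interval == widened
        assert traces[0].overlapping_cns_genes == ["BRAIN1"]

    def test_decision_for_unknown_call_rejected(self):
        decision = ReviewDecision("ghost", GenomicInterval("1", 1, 2), "exclude")
        with pytest.raises(ValueError, match="unknown call"):
            run_cascade([call()], self.cohort, self.db, PERMISSIVE,
                        decisions=[decision])


class TestCascadeInvariants:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.calls = []
        for i in range(60):
            s = int(rng.integers(1, 9_000_000))
            self.calls.append(call(
                start=s, end=s + int(rng.integers(1000, 100_000)),
                lbf=float(rng.uniform(0, 60)),
                n_markers=int(rng.integers(1, 20)),
                sample=f"s{i % 10}",
            ))
        self.cohort = ControlCohort(100, [])
        self.db = PopulationDb([])

    def test_trace_conservation(self):
        retained, traces = run_cascade(
            self.calls, self.cohort, self.db, PERMISSIVE
        )
        failed = [t for t in traces
                  if any(v is Verdict.FAIL for v in t.verdicts.values())]
        assert len(self.calls) == len(retained) + len(failed)

    def test_final_iff_all_evaluated_pass(self):
        _, traces = run_cascade(self.calls, self.cohort, self.db, PERMISSIVE)
        for t in traces:
            evaluated = [v for v in t.verdicts.values()
                         if v is not Verdict.NOT_EVALUATED]
            assert t.final == all(v is Verdict.PASS for v in evaluated)

    def test_not_evaluated_after_first_fail(self):
        _, traces = run_cascade(self.calls, self.cohort, self.db, PERMISSIVE)
        for t in traces:
            seq = [t.verdicts[k] for k in ("I", "II", "III", "IV", "V", "VI",
                                           "VII")]
            if Verdict.FAIL in seq:
                after = seq[seq.index(Verdict.FAIL) + 1:]
                assert all(v is Verdict.NOT_EVALUATED for v in after)

    def test_commuting_criteria_order_independent(self):
        base, _ = run_cascade(self.calls, self.cohort, self.db, PERMISSIVE)
        static = ["I", "II", "III", "V", "VI"]
        for perm in itertools.permutations(static):
            order = list(perm[:3]) + ["IV"] + list(perm[3:]) + ["VII"]
            retained, _ = run_cascade(
                self.calls, self.cohort, self.db, PERMISSIVE, order=order
            )
            assert retained == base

    def test_fully_permissive_config_is_identity(self):
        config = FilterConfig(lbf_min=0.0, min_markers=1,
                              max_control_freq=1.0,
                              dgv_max_full_overlaps=10**9)
        retained, _ = run_cascade(
            self.calls, self.cohort, self.db, PERMISSIVE, config=config
        )
        assert retained == self.calls

    def test_empty_call_set(self):
        retained, traces = run_cascade([], self.cohort, self.db, PERMISSIVE)
        assert retained == [] and traces == []

    def test_review_gates_fixed_in_position(self):
        with pytest.raises(ValueError):
            run_cascade(self.calls, self.cohort, self.db, PERMISSIVE,
                        order=["IV", "I", "II", "III", "V", "VI", "VII"])
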