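"""Unit tests of the estimation pipeline stages: QC, downsampling,
classification rules, relative abundance, outlier removal, weighting,
genome equivalents, bootstrap dispersion, and the closed-form comparator."""

import pytest

from agscensus.ags_core import (
    MappingCutoffs,
    PipelineConfig,
    RaesParams,
    TrainedFamilyParams,
    TrainedModel,
    bootstrap_dispersion,
    classify_reads,
    downsample_and_trim,
    family_ags_estimate,
    family_relative_abundance,
    genome_equivalents,
    qc_filter,
    raes_estimate,
    remove_outliers,
    weighted_ags,
)
from agscensus.align import AlignmentHit
from agscensus.io import Read


def _read(seq, qual=None, rid="r"):
    return Read(rid, seq, qual)


class TestQcFilter:
    def test_dedupe_keeps_first(self):
        reads = [_read("AAA", rid="1"), _read("CCC", rid="2"), _read("AAA", rid="3")]
        out, report = qc_filter(reads, PipelineConfig(dedupe=True))
        assert [r.seq for r in out] == ["AAA", "CCC"]
        assert report["duplicates"] == 1

    def test_mean_quality_filter(self):
        q4 = chr(4 + 33) * 30
        q40 = chr(40 + 33) * 30
        reads = [_read("A" * 30, q4), _read("A" * 30, q40)]
        out, report = qc_filter(reads, PipelineConfig(min_mean_quality=5))
        assert len(out) == 1 and report["low_quality"] == 1

    def test_ambiguous_base_boundary(self):
        # >5% Ns dropped, exactly 5% kept
        six_n = _read("N" * 6 + "A" * 94)
        five_n = _read("N" * 5 + "A" * 95)
        out, report = qc_filter([six_n, five_n], PipelineConfig(max_ambiguous_pct=5))
        assert len(out) == 1 and out[0].seq == five_n.seq
        assert report["ambiguous"] == 1

    def test_fasta_quality_filter_noop(self):
        reads = [_read("A" * 30, None)]
        out, _ = qc_filter(reads, PipelineConfig(min_mean_quality=5))
        assert len(out) == 1


class TestDownsampleTrim:
    def test_first_n_of_sufficient_length(self):
        reads = [_read("A" * n, rid=str(i)) for i, n in enumerate([60, 80, 50, 90, 100])]
        out = downsample_and_trim(reads, n=3, i=70)
        assert [r.id for r in out] == ["1", "3", "4"]
        assert all(len(r.seq) == 70 for r in out)

    def test_shortfall_keeps_all(self):
        reads = [_read("A" * 80, rid=str(i)) for i in range(2)]
        assert len(downsample_and_trim(reads, n=10, i=70)) == 2

    def test_single_read(self):
        assert len(downsample_and_trim([_read("A" * 30)], n=1, i=25)) == 1

    def test_no_qualifying_reads_fatal(self):
        with pytest.raises(ValueError):
            downsample_and_trim([_read("A" * 30)], n=1, i=70)


def _model(cutoffs=MappingCutoffs(30, 0.70, 95.0), c=40.0, fams=("fam1", "fam2")):
    entries = [
        TrainedFamilyParams(f, 100, cutoffs, proportionality_constant=c,
                            weight=1.0 / len(fams))
        for f in fams
    ]
    return TrainedModel("test", entries)


def _hit(fam="fam1", bit=38.0, cov=0.80, pid=60.0):
    return AlignmentHit("r", fam, f"{fam}.t", bit, pid, cov, 1e-8, 1)


class TestClassifyReads:
    def test_passing_hit_assigned(self):
        counts = classify_reads([[_hit()]], _model(), 100)
        assert counts == {"fam1": 1, "fam2": 0}

    def test_identity_above_maximum_rejected(self):
        counts = classify_reads([[_hit(pid=96.0)]], _model(), 100)
        assert counts["fam1"] == 0

    def test_thresholds_inclusive(self):
        counts = classify_reads([[_hit(bit=30.0, cov=0.70, pid=95.0)]], _model(), 100)
        assert counts["fam1"] == 1

    def test_only_top_hit_considered(self):
        # top hit fails identity; the read is not rescued by the second hit
        hits = [[_hit(fam="fam1", bit=50, pid=99.0), _hit(fam="fam2", bit=40)]]
        counts = classify_reads(hits, _model(), 100)
        assert counts == {"fam1": 0, "fam2": 0}

    def test_unknown_family_fatal(self):
        with pytest.raises(ValueError):
            classify_reads([[_hit(fam="mystery")]], _model(), 100)


class TestAbundanceAndEstimate:
    def test_relative_abundance_units(self):
        assert family_relative_abundance(70, 7_000_000) == pytest.approx(1e-5)

    def test_zero_mapped_allowed(self):
        assert family_relative_abundance(0, 100) == 0.0

    def test_zero_library_fatal(self):
        with pytest.raises(ValueError):
            family_relative_abundance(1, 0)

    def test_estimate_is_c_over_r(self):
        assert family_ags_estimate(1e-5, 40.0) == pytest.approx(4.0e6)
        assert family_ags_estimate(2e-5, 40.0) == pytest.approx(2.0e6)

    def test_halving_r_doubles_estimate(self):
        assert family_ags_estimate(5e-6, 40.0) == 2 * family_ags_estimate(1e-5, 40.0)

    def test_zero_r_unestimable(self):
        assert family_ags_estimate(0.0, 40.0) is None


class TestOutliers:
    def test_two_fold_rule(self):
        # 10 / 4.2 = 2.38-fold > 2-fold from the median; floor of 2 so the
        # flagging is not overridden by the survivor floor
        flags = remove_outliers({"a": 4.0e6, "b": 4.2e6, "c": 10.0e6},
                                min_classified_families=2)
        assert flags == {"a": False, "b": False, "c": True}

    def test_all_equal_none_flagged(self):
        flags = remove_outliers({"a": 4e6, "b": 4e6, "c": 4e6})
        assert not any(flags.values())

    def test_floor_enforced(self):
        with pytest.raises(ValueError):
            remove_outliers({"a": 4.0e6, "b": 4.2e6}, min_classified_families=3)

    def test_survivor_floor_retains_closest(self):
        est = {"a": 1.0, "b": 10.0, "c": 100.0}
        flags = remove_outliers(est, min_classified_families=3)
        assert not any(flags.values())


class TestWeightedAgs:
    def test_weighted_average(self):
        v = weighted_ags({"a": 4.0e6, "b": 4.4e6}, {"a": 0.25, "b": 0.75})
        assert v == pytest.approx(4.3e6)

    def test_single_survivor(self):
        assert weighted_ags({"a": 3e6}, {"a": 0.1}) == pytest.approx(3e6)

    def test_uniform_weights_are_mean(self):
        v = weighted_ags({"a": 2e6, "b": 4e6}, {"a": 0.5, "b": 0.5})
        assert v == pytest.approx(3e6)

    def test_zero_weights_fall_back_to_mean(self):
        v = weighted_ags({"a": 2e6, "b": 4e6}, {"a": 0.0, "b": 0.0})
        assert v == pytest.approx(3e6)


class TestGenomeEquivalents:
    def test_quotient(self):
        assert genome_equivalents(1e9, 4e6) == pytest.approx(250)
        assert genome_equivalents(8.4e9, 4.2e6) == pytest.approx(2000)

    def test_identity(self):
        assert genome_equivalents(4e6, 4e6) == 1.0


class TestBootstrapDispersion:
    def test_degenerate_estimator_zero_dispersion(self):
        reads = [_read("A" * 30, rid=str(i)) for i in range(100)]
        out = bootstrap_dispersion(reads, lambda sub: 4.0e6, [10, 50], iterations=5, seed=1)
        assert out[10]["dispersion"] == 0.0
        assert out[50]["dispersion"] == 0.0

    def test_deterministic_under_seed(self):
        reads = [_read("A" * 30, rid=str(i)) for i in range(50)]
        est = lambda sub: 1e6 + 1000 * len({r.id for r in sub} & {"0", "1", "2"})
        a = bootstrap_dispersion(reads, est, [10], iterations=20, seed=9)
        b = bootstrap_dispersion(reads, est, [10], iterations=20, seed=9)
        assert a == b

    def test_failed_iterations_recorded(self):
        def flaky(sub):
            if any(r.id == "0" in r.id for r in sub):
                raise ValueError("floor")
            return 1e6

        reads = [_read("A" * 30, rid=str(i)) for i in range(10)]
        out = bootstrap_dispersion(reads, flaky, [10], iterations=3, seed=2)
        assert out[10]["missing"] == 3

    def test_oversized_sample_fatal(self):
        with pytest.raises(ValueError):
            bootstrap_dispersion([_read("A" * 30)], lambda s: 1.0, [5], iterations=2)


class TestRaes:
    def test_hand_evaluated_point(self):
        # 4230 * 100**-0.733 = 144.65...; 21.2 + 144.65/1.4466 = 121.2
        assert raes_estimate(1.4466, 100.0) == pytest.approx(121.2, abs=0.05)

    def test_limit_is_a(self):
        assert raes_estimate(1e12, 100.0) == pytest.approx(21.2, abs=1e-6)

    def test_doubling_density_halves_second_term(self):
        p = RaesParams()
        one = raes_estimate(2.0, 100.0) - p.a
        two = raes_estimate(4.0, 100.0) - p.a
        assert one == pytest.approx(2 * two)

    def test_nonpositive_density_fatal(self):
        with pytest.raises(ValueError):
            raes_estimate(0.0, 100.0)


class TestTrainedModel:
    def test_weights_must_sum_to_one(self):
        c = MappingCutoffs(30, 0.7, 100)
        entries = [
            TrainedFamilyParams("a", 100, c, 40.0, 0.7),
            TrainedFamilyParams("b", 100, c, 40.0, 0.7),
        ]
        with pytest.raises(ValueError):
            TrainedModel("t", entries)

    def test_dispatch_never_extrapolates_upward(self):
        m = _model()
        assert m.dispatch_length(100) == 100
        assert m.dispatch_length(140) == 100
        with pytest.raises(ValueError):
            m.dispatch_length(70)
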