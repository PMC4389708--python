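"""Calibration-stage tests: training-library simulation, error metrics,
cutoff grid search, constant fitting, and the weight optimizer (checked
against a brute-force simplex-grid oracle)."""

import numpy as np
import pytest

from agscensus.ags_core import MappingCutoffs
from agscensus.simulate import CommunityMember, generate_genome
from agscensus.train import (
    AlignedLibrary,
    CutoffGrid,
    _project_simplex,
    fit_constants,
    fit_weights,
    optimize_cutoffs,
    signed_error,
    simulate_training_libraries,
    unsigned_error,
)

from _oracle import simplex_grid


class TestErrorMetrics:
    def test_unsigned(self):
        assert unsigned_error(4.2, 4.0) == pytest.approx(0.05)

    def test_signed(self):
        assert signed_error(3.8, 4.0) == pytest.approx(-0.05)

    def test_exact_is_zero(self):
        assert unsigned_error(4.0, 4.0) == 0.0 == signed_error(4.0, 4.0)


class TestTrainingLibraries:
    @pytest.fixture()
    def genomes(self, tiny_db):
        g = generate_genome(tiny_db, size=200_000, divergence=0.02, seed=31,
                            genome_id="gA")
        return [g]

    def test_read_count_from_coverage(self, genomes):
        libs = simulate_training_libraries(genomes, [500], coverage=200.0, seed=1)
        # N = G * S / L = 200 * 200000 / 500
        assert libs[0].read_length == 500
        assert len(libs[0].reads) == 80_000

    def test_short_lengths_are_3prime_trims(self, genomes):
        libs = simulate_training_libraries(genomes, [100, 500], coverage=2.0, seed=2)
        by_len = {l.read_length: l for l in libs}
        assert len(by_len[100].reads) == len(by_len[500].reads)
        for short, full in zip(by_len[100].reads, by_len[500].reads):
            assert short.seq == full.seq[:100]

    def test_library_count_is_genomes_times_lengths(self, tiny_db):
        gs = [
            generate_genome(tiny_db, size=100_000, divergence=0.02, seed=40 + i,
                            genome_id=f"g{i}")
            for i in range(3)
        ]
        libs = simulate_training_libraries(gs, [50, 100], coverage=1.0, seed=3)
        assert len(libs) == 6

    def test_too_short_genome_skipped(self, tiny_db):
        short = CommunityMember("tiny", 30_000, sequence="ACGT" * 7500)
        ok = generate_genome(tiny_db, size=100_000, divergence=0.0, seed=50,
                             genome_id="ok")
        libs = simulate_training_libraries([short, ok], [50_000 // 1000 * 10 + 49_000], 1.0)
        assert {l.genome_id for l in libs} == {"ok"}


def _aligned_lib(gid, truth, fam_data, read_length=100, n_reads=10_000):
    """fam_data: list of (family_idx, bit, cov, pid) tuples."""
    arr = np.array(fam_data, dtype=float)
    if len(arr) == 0:
        arr = np.zeros((0, 4))
    return AlignedLibrary(
        genome_id=gid,
        true_ags=truth,
        read_length=read_length,
        n_reads=n_reads,
        top_family=arr[:, 0].astype(np.int32),
        top_bit=arr[:, 1],
        top_cov=arr[:, 2],
        top_pid=arr[:, 3],
    )


class TestOptimizeCutoffs:
    def test_lower_error_combo_wins(self):
        # family 0: library A has 2 strong hits, library B has 1 -> with all
        # hits passing, C/R is inconsistent between libraries; a cutoff that
        # drops B's weak hit entirely would zero it out (infinite error)
        grid = CutoffGrid(bit_scores=(20, 60), coverages=(0.5,), max_pids=(100.0,))
        libA = _aligned_lib("A", 1e6, [(0, 80, 0.9, 100), (0, 80, 0.9, 100)])
        libB = _aligned_lib("B", 2e6, [(0, 40, 0.9, 100)])
        cutoffs, untrainable = optimize_cutoffs([libA, libB], grid, ["f0"])
        assert not untrainable
        assert cutoffs["f0"].min_bit_score == 20.0

    def test_tied_combos_resolve_least_stringent(self):
        # all hits far above every grid point: ties everywhere
        grid = CutoffGrid(bit_scores=(20, 40), coverages=(0.4, 0.6), max_pids=(95.0, 100.0))
        libs = [
            _aligned_lib("A", 1e6, [(0, 90, 0.95, 80.0)] * 5),
            _aligned_lib("B", 2e6, [(0, 90, 0.95, 80.0)] * 3),
        ]
        cutoffs, _ = optimize_cutoffs(libs, grid, ["f0"])
        c = cutoffs["f0"]
        assert (c.min_bit_score, c.min_alignment_coverage, c.max_percent_identity) == (
            20.0, 0.4, 100.0,
        )

    def test_family_with_no_hits_flagged_untrainable(self):
        grid = CutoffGrid(bit_scores=(20,), coverages=(0.5,), max_pids=(100.0,))
        libs = [_aligned_lib("A", 1e6, []), _aligned_lib("B", 2e6, [])]
        _, untrainable = optimize_cutoffs(libs, grid, ["f0"])
        assert untrainable == {"f0"}


class TestFitConstants:
    def test_median_over_libraries(self):
        cut = {"f0": MappingCutoffs(20, 0.4, 100.0)}
        libs = []
        for gid, truth, n_hits in [("A", 1e6, 38), ("B", 1e6, 40), ("C", 1e6, 44)]:
            libs.append(
                _aligned_lib(gid, truth, [(0, 90, 0.9, 100)] * n_hits,
                             read_length=100, n_reads=10)
            )
        c = fit_constants(libs, cut, ["f0"])["f0"]
        # per-library C = truth * n / (10 * 100); median of {38,40,44} -> 40
        assert c == pytest.approx(1e6 * 40 / 1000)

    def test_all_zero_fatal(self):
        cut = {"f0": MappingCutoffs(20, 0.4, 100.0)}
        with pytest.raises(ValueError):
            fit_constants([_aligned_lib("A", 1e6, [])], cut, ["f0"])


class TestFitWeights:
    def test_unbiased_family_dominates(self):
        """One exactly unbiased family among 2x-biased ones should take
        nearly all the weight; verified against a 0.05-resolution simplex
        grid search."""
        rng = np.random.default_rng(3)
        truths = rng.uniform(1e6, 5e6, 15)
        est = np.column_stack([truths, 2.0 * truths, 2.0 * truths])

        def objective(w):
            w = np.asarray(w)
            if w.sum() == 0:
                return np.inf
            pred = est @ w / w.sum()
            return np.median(np.abs(pred - truths) / truths)

        best_grid = min(simplex_grid(3, 0.05), key=objective)
        weights, achieved = fit_weights(est, truths)
        assert weights[0] >= 0.9
        assert best_grid[0] >= 0.9
        assert achieved <= objective(best_grid) + 1e-9

    def test_identical_estimators_return_uniform(self):
        truths = np.array([1e6, 2e6, 3e6])
        est = np.column_stack([truths * 1.1] * 4)
        weights, _ = fit_weights(est, truths)
        assert weights == pytest.approx(np.full(4, 0.25))

    def test_never_worse_than_uniform(self):
        rng = np.random.default_rng(5)
        truths = rng.uniform(1e6, 5e6, 20)
        est = truths[:, None] * rng.lognormal(0, 0.3, (20, 6))

        def objective(w):
            pred = est @ w / np.sum(w)
            return np.median(np.abs(pred - truths) / truths)

        weights, achieved = fit_weights(est, truths)
        assert achieved <= objective(np.full(6, 1 / 6)) + 1e-12
        assert weights.sum() == pytest.approx(1.0)


class TestEvaluateHoldout:
    @pytest.fixture(scope="class")
    def holdout_setup(self, request):
        """A tiny labeled panel with a quick model trained on half of it."""
        from agscensus.ags_core import PipelineConfig
        from agscensus.marker_db import demo_database
        from agscensus.simulate import (
            SimulationConfig,
            build_community,
            generate_taxon_panel,
            simulate_reads,
        )
        from agscensus.train import train_model

        markers = demo_database(n_families=6, protein_length=120, seed=61)
        panel_db, genomes = generate_taxon_panel(
            markers, n_classes=2, genera_per_class=2, species_per_genus=2,
            size_range=(60_000, 90_000), seed=61,
        )
        train_g = [g for g in genomes if g.taxonomy["class"] == "class00"]
        test_g = [g for g in genomes if g.taxonomy["class"] == "class01"]
        model = train_model(train_g, panel_db, read_lengths=[100], coverage=8.0, seed=61)
        # only one genus of the held-out class, so species-level exclusion
        # removes strictly fewer sequences than class-level exclusion
        test_g = [g for g in test_g if g.taxonomy["genus"].endswith("genus00")]
        comm = build_community(test_g, abundances=[0.5] * len(test_g))
        reads, _ = simulate_reads(
            comm, SimulationConfig(read_length=100, total_coverage=25.0, seed=62)
        )
        cfg = PipelineConfig(n_reads=10**6, read_length=100, min_classified_families=3)
        return {"db": panel_db, "model": model, "libs": [(comm, reads)], "cfg": cfg}

    def test_level_none_matches_plain_estimation(self, holdout_setup):
        from agscensus.ags_core import estimate_ags
        from agscensus.train import evaluate_holdout

        s = holdout_setup
        res = evaluate_holdout(s["model"], s["db"], s["libs"], "none", s["cfg"])
        comm, reads = s["libs"][0]
        plain = estimate_ags(reads, s["db"], s["model"], s["cfg"])
        assert res[0]["estimated_ags"] == pytest.approx(plain.ags)
        assert res[0]["n_excluded_sequences"] == 0

    def test_exclusion_grows_with_level_and_error_does_not_shrink(self, holdout_setup):
        from agscensus.train import evaluate_holdout

        s = holdout_setup
        by_level = {
            lvl: evaluate_holdout(s["model"], s["db"], s["libs"], lvl, s["cfg"])[0]
            for lvl in ("none", "species", "class")
        }
        assert (
            by_level["none"]["n_excluded_sequences"]
            < by_level["species"]["n_excluded_sequences"]
            < by_level["class"]["n_excluded_sequences"]
        )
        # errors stay bounded even at class-level exclusion on this panel
        for lvl, r in by_level.items():
            assert r["unsigned_error"] < 0.25, (lvl, r["unsigned_error"])

    def test_unknown_level_fatal(self, holdout_setup):
        from agscensus.train import evaluate_holdout

        with pytest.raises(ValueError):
            evaluate_holdout(
                holdout_setup["model"], holdout_setup["db"],
                holdout_setup["libs"], "kingdom", holdout_setup["cfg"],
            )


def test_project_simplex():
    p = _project_simplex(np.array([0.5, 0.5, 2.0]))
    assert p.sum() == pytest.approx(1.0)
    assert (p >= 0).all()
    q = _project_simplex(np.array([0.2, 0.3, 0.5]))
    assert q == pytest.approx([0.2, 0.3, 0.5])
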