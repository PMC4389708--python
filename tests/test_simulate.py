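"""Tests of the synthetic community and read simulator: truth bookkeeping,
entropy tiers, coverage arithmetic, determinism, and the error model."""

import math

import numpy as np
import pytest

from agscensus.simulate import (
    CommunityMember,
    CommunityProfile,
    SimulationConfig,
    SyntheticMarkerSpec,
    build_community,
    generate_genome,
    generate_marker_families,
    generate_taxon_panel,
    geometric_abundances,
    mix_contaminants,
    shannon_entropy,
    simulate_reads,
    true_ags,
)


def _member(gid, size, abund, seq=None, markers=True):
    return CommunityMember(gid, size, relative_abundance=abund, sequence=seq,
                           carries_markers=markers)


class TestTrueAgs:
    def test_two_member_mean(self):
        comm = CommunityProfile(
            [_member("bt", 6_500_000, 0.5), _member("ms", 1_900_000, 0.5)]
        )
        assert true_ags(comm) == pytest.approx(4_200_000)

    def test_single_genome_identity(self):
        comm = CommunityProfile([_member("g", 3_000_000, 1.0)])
        assert true_ags(comm) == pytest.approx(3_000_000)

    def test_viral_members_do_not_count(self):
        comm = CommunityProfile(
            [_member("cell", 3_000_000, 0.5), _member("phage", 60_000, 0.5, markers=False)]
        )
        assert true_ags(comm) == pytest.approx(3_000_000)

    def test_all_viral_is_fatal(self):
        comm = CommunityProfile([_member("phage", 60_000, 1.0, markers=False)])
        with pytest.raises(ValueError):
            true_ags(comm)


class TestShannonEntropy:
    def test_uniform_20_members(self):
        assert shannon_entropy([1 / 20] * 20) == pytest.approx(math.log2(20), abs=5e-3)
        assert round(shannon_entropy([1 / 20] * 20), 2) == 4.32

    def test_single_member(self):
        assert shannon_entropy([1.0]) == 0.0

    def test_uniform_two(self):
        assert shannon_entropy([0.5, 0.5]) == pytest.approx(1.0)

    def test_negative_is_fatal(self):
        with pytest.raises(ValueError):
            shannon_entropy([1.5, -0.5])


class TestMarkerGeneration:
    def test_deterministic_under_seed(self):
        spec = SyntheticMarkerSpec(n_families=30, ancestral_protein_length=200, seed=1)
        a = generate_marker_families(spec)
        b = generate_marker_families(spec)
        assert [f.proteins for f in a.families] == [f.proteins for f in b.families]

    def test_single_family(self):
        db = generate_marker_families(SyntheticMarkerSpec(n_families=1, seed=2))
        assert len(db.families) == 1

    def test_ancestors_independent_of_divergence(self):
        a = generate_marker_families(SyntheticMarkerSpec(per_genome_divergence=0.0, seed=3))
        b = generate_marker_families(SyntheticMarkerSpec(per_genome_divergence=0.5, seed=3))
        assert [f.proteins for f in a.families] == [f.proteins for f in b.families]


class TestGenomeGeneration:
    def test_exact_size_and_marker_loci(self, tiny_db):
        g = generate_genome(tiny_db, size=100_000, divergence=0.05, seed=4)
        assert len(g.sequence) == 100_000
        assert g.genome_size == 100_000

    def test_viral_like_has_no_markers(self, tiny_db):
        g = generate_genome(tiny_db, size=50_000, divergence=0.0, seed=5,
                            carries_markers=False)
        assert g.carries_markers is False

    def test_deterministic(self, tiny_db):
        a = generate_genome(tiny_db, size=60_000, divergence=0.1, seed=6)
        b = generate_genome(tiny_db, size=60_000, divergence=0.1, seed=6)
        assert a.sequence == b.sequence

    def test_too_small_is_fatal(self, tiny_db):
        with pytest.raises(ValueError):
            generate_genome(tiny_db, size=1000, divergence=0.0, seed=7)


class TestBuildCommunity:
    @pytest.mark.parametrize("tier,target", [("high", 4.32), ("medium", 2.75), ("low", 1.08)])
    def test_tier_entropies(self, tier, target):
        genomes = [_member(f"g{i}", 100_000, 0.0) for i in range(20)]
        comm = build_community(genomes, complexity=tier, seed=1)
        assert shannon_entropy(comm.abundances()) == pytest.approx(target, abs=0.01)

    def test_explicit_abundances_honored(self):
        genomes = [_member("a", 1000, 0.0), _member("b", 2000, 0.0)]
        comm = build_community(genomes, abundances=[0.7, 0.3])
        assert list(comm.abundances()) == pytest.approx([0.7, 0.3])

    def test_tiers_require_20_members(self):
        genomes = [_member(f"g{i}", 1000, 0.0) for i in range(5)]
        with pytest.raises(ValueError):
            build_community(genomes, complexity="medium")

    def test_geometric_bisection_out_of_range(self):
        with pytest.raises(ValueError):
            geometric_abundances(20, 5.0)


@pytest.fixture(scope="module")
def community(tiny_db):
    genomes = [
        generate_genome(tiny_db, size=30_000, divergence=0.02, seed=10 + i,
                        genome_id=f"g{i}")
        for i in range(2)
    ]
    return build_community(genomes, abundances=[0.5, 0.5])


class TestSimulateReads:
    def test_read_counts_follow_coverage_formula(self, community):
        cfg = SimulationConfig(read_length=100, total_coverage=4.0, seed=1)
        reads, truth = simulate_reads(community, cfg)
        # N_ij = round(R_i * G_j * S_i / L_j) = round(0.5 * 4 * 30000 / 100)
        for row in truth["members"]:
            assert row["n_reads"] == 600
        assert len(reads) == 1200

    def test_total_bases_match_target(self, community):
        cfg = SimulationConfig(read_length=50, total_coverage=6.0, seed=2)
        reads, truth = simulate_reads(community, cfg)
        want = cfg.total_coverage * sum(
            m.relative_abundance * m.genome_size for m in community.members
        )
        got = sum(len(r.seq) for r in reads)
        assert abs(got - want) <= 50 * len(truth["members"])

    def test_error_free_reads_are_substrings(self, community):
        cfg = SimulationConfig(read_length=80, total_coverage=1.0, seed=3)
        reads, _ = simulate_reads(community, cfg)
        seqs = {}
        for m in community.members:
            rc = m.sequence.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            seqs[m.genome_id] = (m.sequence + m.sequence[:80], rc + rc[:80])
        for r in reads[:200]:
            gid = r.id.split("|")[0]
            assert r.seq in seqs[gid][0] or r.seq in seqs[gid][1]

    def test_deterministic_fastq(self, community):
        cfg = SimulationConfig(read_length=60, total_coverage=2.0, seed=4)
        a, _ = simulate_reads(community, cfg)
        b, _ = simulate_reads(community, cfg)
        assert a == b

    def test_truth_records_true_ags(self, community):
        cfg = SimulationConfig(read_length=60, total_coverage=1.0, seed=5)
        _, truth = simulate_reads(community, cfg)
        assert truth["true_ags"] == pytest.approx(true_ags(community))

    def test_errors_change_reads_at_expected_rate(self, community):
        cfg0 = SimulationConfig(read_length=100, total_coverage=2.0, seed=6)
        cfg1 = SimulationConfig(read_length=100, total_coverage=2.0, seed=6,
                                error_rate=0.02)
        clean, _ = simulate_reads(community, cfg0)
        noisy, _ = simulate_reads(community, cfg1)
        assert len(clean) == len(noisy)
        diffs = [
            sum(a != b for a, b in zip(c.seq, n.seq))
            for c, n in zip(clean, noisy)
        ]
        mean_diff = np.mean(diffs)
        # substitutions alone give ~2 per 100 bp; an indel (prob ~1/3 per
        # read) misaligns the rest of the read, adding ~50 mismatches
        assert 1.0 < mean_diff < 30.0
        assert all(len(r.seq) == 100 for r in noisy)

    def test_read_length_longer_than_genome_fatal(self, tiny_db):
        g = generate_genome(tiny_db, size=30_000, divergence=0.0, seed=1, genome_id="g")
        small = CommunityMember("tiny", 100, relative_abundance=0.5, sequence="A" * 100)
        comm = CommunityProfile([
            CommunityMember("g", 30_000, relative_abundance=0.5, sequence=g.sequence),
            small,
        ])
        with pytest.raises(ValueError):
            simulate_reads(comm, SimulationConfig(read_length=500, total_coverage=1.0, seed=1))


class TestMixContaminants:
    def _reads(self, n, tag):
        from agscensus.io import Read

        return [Read(f"{tag}{i}", "ACGT" * 10) for i in range(n)]

    def test_zero_fraction_is_identity(self):
        lib = self._reads(10, "a")
        assert mix_contaminants(lib, self._reads(10, "b"), 0.0) == lib

    def test_half_replaces_half(self):
        lib = self._reads(1000, "a")
        cont = self._reads(600, "v")
        mixed = mix_contaminants(lib, cont, 0.5, seed=1)
        assert len(mixed) == 1000
        assert sum(r.id.startswith("v") for r in mixed) == 500

    def test_insufficient_contaminants_fatal(self):
        with pytest.raises(ValueError):
            mix_contaminants(self._reads(100, "a"), self._reads(3, "v"), 0.5)


class TestTaxonPanel:
    def test_labels_and_divergence_structure(self, tiny_db):
        panel_db, genomes = generate_taxon_panel(
            tiny_db, n_classes=2, genera_per_class=2, species_per_genus=2,
            size_range=(40_000, 60_000), seed=3,
        )
        assert len(genomes) == 8
        assert panel_db.n_proteins == 8 * len(tiny_db.families)
        labels = {g.taxonomy["class"] for g in genomes}
        assert len(labels) == 2
        # within-genus divergence < cross-class divergence for family 0
        fam = panel_db.families[0]
        seqs = dict(fam.proteins)

        def div(a, b):
            return sum(x != y for x, y in zip(a, b)) / len(a)

        same_genus = div(seqs[f"{fam.family_id}.c00g00s00"], seqs[f"{fam.family_id}.c00g00s01"])
        cross_class = div(seqs[f"{fam.family_id}.c00g00s00"], seqs[f"{fam.family_id}.c01g00s00"])
        assert same_genus < cross_class
        assert 0.005 < same_genus < 0.12
        assert 0.08 < cross_class < 0.25
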