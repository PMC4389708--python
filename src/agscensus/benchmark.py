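"""End-to-end benchmark of the estimator on the synthetic taxonomic panel.

This drives the whole stack: a labeled panel of genomes in a three-level
synthetic taxonomy, calibration on half of the panel, and estimation on
medium-complexity communities of the held-out genomes — with and without
taxonomic exclusion of matching marker references (the novel-taxon
scenario).  Accuracy is summarized as the median unsigned error over the
test communities.

Problem sizes follow the package's desk-scale study conditions: 30 marker
families of 200 aa, 40 genomes of 100-500 kb (4 classes x 2 genera x 5
species, 2.5% substitution per taxonomy branch), 20 training genomes at 20x
coverage, and 20 test communities of ~100k error-free reads each.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .ags_core import PipelineConfig
from .align import get_index, search_reads
from .simulate import (
    CommunityProfile,
    SimulationConfig,
    SyntheticMarkerSpec,
    build_community,
    generate_marker_families,
    generate_taxon_panel,
    simulate_reads,
)
from .train import CutoffGrid, evaluate_holdout, train_model

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkConfig:
    n_families: int = 30
    protein_length: int = 200
    n_classes: int = 4
    genera_per_class: int = 2
    species_per_genus: int = 5
    branch_divergence: float = 0.025
    size_range: tuple[int, int] = (100_000, 500_000)
    train_coverage: float = 20.0
    n_communities: int = 20
    reads_per_community: int = 100_000
    complexity: str = "medium"
    grid: CutoffGrid = field(default_factory=CutoffGrid)


def build_panel(seed: int, cfg: BenchmarkConfig = BenchmarkConfig()):
    """The labeled marker panel plus a train/test genome split.

    Training genomes come from the first half of the classes, test genomes
    from the second half, so class-level exclusion of test taxa leaves the
    training classes' (most diverged) marker variants in the database.
    """
    markers = generate_marker_families(
        SyntheticMarkerSpec(
            n_families=cfg.n_families,
            ancestral_protein_length=cfg.protein_length,
            seed=seed,
        )
    )
    panel_db, genomes = generate_taxon_panel(
        markers,
        n_classes=cfg.n_classes,
        genera_per_class=cfg.genera_per_class,
        species_per_genus=cfg.species_per_genus,
        branch_divergence=cfg.branch_divergence,
        size_range=cfg.size_range,
        seed=seed,
    )
    train_classes = {f"class{c:02d}" for c in range(cfg.n_classes // 2)}
    train_genomes = [g for g in genomes if g.taxonomy["class"] in train_classes]
    test_genomes = [g for g in genomes if g.taxonomy["class"] not in train_classes]
    return markers, panel_db, train_genomes, test_genomes


def make_communities(
    test_genomes, n_communities: int, seed: int, complexity: str = "medium"
) -> list[CommunityProfile]:
    """Communities of the held-out genomes; the abundance ranks are permuted
    per community so each has a different true AGS."""
    return [
        build_community(test_genomes, complexity=complexity, seed=seed * 10_000 + ci)
        for ci in range(n_communities)
    ]


def community_reads(community: CommunityProfile, read_length: int, n_reads: int, seed: int):
    """An error-free library of ~n_reads reads (total coverage chosen from
    the abundance-weighted community size)."""
    weighted_bp = sum(m.relative_abundance * m.genome_size for m in community.members)
    coverage = n_reads * read_length / weighted_bp
    cfg = SimulationConfig(
        read_length=read_length, total_coverage=coverage, error_rate=0.0, seed=seed
    )
    return simulate_reads(community, cfg)[0]


def run_benchmark(
    seed: int,
    cfg: BenchmarkConfig = BenchmarkConfig(),
    read_lengths=(50, 100, 250, 500),
    holdout_levels=("species", "genus", "class"),
    holdout_length: int = 100,
) -> dict:
    """Train on the panel and measure median unsigned errors.

    Returns per-length no-exclusion medians plus, at ``holdout_length``,
    per-level exclusion medians (all in fractional units).  Each community
    is searched once against the full database; exclusion levels reuse the
    hits with the excluded targets masked, which is exactly equivalent to
    searching the reduced database.
    """
    t_start = time.time()
    markers, panel_db, train_genomes, test_genomes = build_panel(seed, cfg)
    index = get_index(panel_db)
    logger.info("panel built (%.1fs); training...", time.time() - t_start)
    model = train_model(
        train_genomes,
        panel_db,
        read_lengths=sorted(set(read_lengths)),
        coverage=cfg.train_coverage,
        grid=cfg.grid,
        seed=seed,
    )
    logger.info("model trained (%.1fs total)", time.time() - t_start)
    communities = make_communities(
        test_genomes, cfg.n_communities, seed, complexity=cfg.complexity
    )
    out: dict = {"seed": seed, "median_unsigned_error": {}, "holdout": {}}
    for L in sorted(set(read_lengths)):
        libraries = []
        hits_list = []
        for ci, comm in enumerate(communities):
            reads = community_reads(
                comm, L, cfg.reads_per_community, seed=seed * 10_000 + 3_000 + ci
            )
            hits = search_reads(reads, index)
            libraries.append((comm, reads))
            hits_list.append(hits)
        pipe_cfg = PipelineConfig(
            n_reads=cfg.reads_per_community * 2, read_length=L
        )
        levels = ["none"] + (
            list(holdout_levels) if L == holdout_length else []
        )
        for level in levels:
            res = evaluate_holdout(
                model, panel_db, libraries, level, pipe_cfg, hits_list=hits_list
            )
            med = float(np.median([r["unsigned_error"] for r in res]))
            if level == "none":
                out["median_unsigned_error"][L] = med
            else:
                out["holdout"][level] = med
            logger.info(
                "L=%d level=%s median unsigned error %.4f (%.1fs total)",
                L, level, med, time.time() - t_start,
            )
        del libraries, hits_list
    out["runtime_s"] = time.time() - t_start
    return out
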