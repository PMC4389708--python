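"""Calibration of the estimator by simulation: grid-searched mapping
cutoffs, median-fitted proportionality constants, and simplex-constrained
family weights, plus the taxonomic-holdout evaluation harness.

The three stages mirror how the estimator is used: (1) single-genome
libraries with known AGS are simulated and aligned once against the marker
database; (2) for every family and read length a grid of (min bit score,
min coverage, max identity) cutoffs is scored by the median unsigned error
of the family's own AGS estimates across libraries, fitting a provisional
proportionality constant per grid point; (3) with cutoffs fixed, C is the
median of true_AGS * R across libraries, and the per-family weights minimize
the median unsigned error of the weighted estimate.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .ags_core import (
    MappingCutoffs,
    PipelineConfig,
    TrainedFamilyParams,
    TrainedModel,
    estimate_ags,
)
from .align import HitTable, PeptideIndex, get_index, search_reads
from .io import Read
from .simulate import (
    CommunityMember,
    CommunityProfile,
    SimulationConfig,
    simulate_reads,
)

logger = logging.getLogger(__name__)


@dataclass
class TrainingLibrary:
    """A single-genome shotgun library with known AGS (= the genome size)."""

    genome_id: str
    true_ags: float
    read_length: int
    reads: list[Read]
    taxon_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.true_ags <= 0:
            raise ValueError("true_ags must be positive")


@dataclass(frozen=True)
class CutoffGrid:
    bit_scores: tuple = tuple(range(20, 61, 5))
    coverages: tuple = tuple(round(0.40 + 0.05 * i, 2) for i in range(12))
    max_pids: tuple = (80.0, 85.0, 90.0, 95.0, 98.0, 100.0)

    def __post_init__(self) -> None:
        if not (self.bit_scores and self.coverages and self.max_pids):
            raise ValueError("grid axes must be non-empty")

    def combinations(self):
        return list(itertools.product(self.bit_scores, self.coverages, self.max_pids))


def unsigned_error(est: float, truth: float) -> float:
    if truth <= 0:
        raise ValueError("truth must be positive")
    return abs(est - truth) / truth


def signed_error(est: float, truth: float) -> float:
    if truth <= 0:
        raise ValueError("truth must be positive")
    return (est - truth) / truth


def simulate_training_libraries(
    genomes: Sequence[CommunityMember],
    read_lengths: Sequence[int],
    coverage: float,
    seed: int = 0,
) -> list[TrainingLibrary]:
    """One error-free library per genome at the longest read length; shorter
    lengths are derived by 3'-trimming the same reads (read counts are
    preserved across lengths)."""
    lengths = sorted(set(read_lengths), reverse=True)
    max_len = lengths[0]
    out: list[TrainingLibrary] = []
    for gi, g in enumerate(genomes):
        if g.genome_size < max_len:
            logger.warning("genome %s shorter than %d bp, skipped", g.genome_id, max_len)
            continue
        member = CommunityMember(
            g.genome_id,
            g.genome_size,
            relative_abundance=1.0,
            sequence=g.sequence,
            carries_markers=g.carries_markers,
            taxonomy=g.taxonomy,
        )
        community = CommunityProfile([member], complexity_tag="custom")
        cfg = SimulationConfig(
            read_length=max_len,
            total_coverage=coverage,
            error_rate=0.0,
            seed=int(np.random.default_rng([seed, 103, gi]).integers(0, 2**31 - 1)),
        )
        reads, _truth = simulate_reads(community, cfg)
        for L in lengths:
            trimmed = (
                reads
                if L == max_len
                else [Read(r.id, r.seq[:L], r.qual[:L] if r.qual else None) for r in reads]
            )
            out.append(
                TrainingLibrary(
                    genome_id=g.genome_id,
                    true_ags=float(g.genome_size),
                    read_length=L,
                    reads=trimmed,
                    taxon_labels=g.taxonomy,
                )
            )
    if not out:
        raise ValueError("no training libraries could be simulated")
    return out


@dataclass
class AlignedLibrary:
    """Cached per-read top hits of one training library (alignments are run
    once and reused across every cutoff-grid point)."""

    genome_id: str
    true_ags: float
    read_length: int
    n_reads: int
    top_family: np.ndarray  # -1 for unhit reads
    top_bit: np.ndarray
    top_cov: np.ndarray
    top_pid: np.ndarray

    @property
    def library_bp(self) -> int:
        return self.n_reads * self.read_length


def align_library(lib: TrainingLibrary, index: PeptideIndex) -> AlignedLibrary:
    hits = search_reads(lib.reads, index)
    fam, bit, cov, pid = hits.top_hits()
    keep = fam >= 0
    return AlignedLibrary(
        genome_id=lib.genome_id,
        true_ags=lib.true_ags,
        read_length=lib.read_length,
        n_reads=len(lib.reads),
        top_family=fam[keep].astype(np.int32),
        top_bit=bit[keep],
        top_cov=cov[keep],
        top_pid=pid[keep],
    )


def _family_grid_errors(
    libs: Sequence[AlignedLibrary], fam_idx: int, combos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(combo, library) unsigned errors for one family.

    For each combo a provisional C (median of true_ags * R over libraries
    with R > 0) is fitted before errors are computed; libraries with R = 0
    get an infinite error.  Also returns the per-combo fraction of
    zero-count libraries.
    """
    bs, cv, mp = combos[:, 0], combos[:, 1], combos[:, 2]
    n_c = len(combos)
    n_l = len(libs)
    rmat = np.zeros((n_c, n_l))
    for li, lib in enumerate(libs):
        sel = lib.top_family == fam_idx
        if sel.any():
            b = lib.top_bit[sel][:, None]
            c = lib.top_cov[sel][:, None]
            p = lib.top_pid[sel][:, None]
            counts = ((b >= bs) & (c >= cv) & (p <= mp)).sum(axis=0)
        else:
            counts = np.zeros(n_c)
        rmat[:, li] = counts / lib.library_bp
    truths = np.array([lib.true_ags for lib in libs])
    c_lib = truths[None, :] * rmat  # per-library C, defined where R > 0
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        c_masked = np.where(rmat > 0, c_lib, np.nan)
        c_prov = np.nanmedian(c_masked, axis=1)
    err = np.full((n_c, n_l), np.inf)
    ok = (rmat > 0) & np.isfinite(c_prov)[:, None]
    est = np.zeros_like(rmat)
    est[ok] = c_prov[np.nonzero(ok)[0]] / rmat[ok]
    err[ok] = np.abs(est[ok] - truths[np.nonzero(ok)[1]]) / truths[np.nonzero(ok)[1]]
    zero_frac = (rmat == 0).mean(axis=1)
    return err, zero_frac


def noise_floor_bits(read_length: int, database_size_aa: int, max_expect: float = 0.01) -> float:
    """Bit score below which chance alignments are expected: the smallest
    bit score with E = m * n * 2**-bit <= max_expect for a translated read
    of the given length."""
    m = max(read_length // 3, 1)
    return float(np.log2(m * database_size_aa / max_expect))


def optimize_cutoffs(
    libs: Sequence[AlignedLibrary],
    grid: CutoffGrid,
    family_names: Sequence[str],
    database_size_aa: int | None = None,
) -> tuple[dict[str, MappingCutoffs], set[str]]:
    """Per-family cutoffs minimizing the median unsigned error across
    training libraries.

    Among grid points whose median error is within one standard error of the
    minimum, the least stringent one is chosen — lowest coverage, then
    highest max identity, then lowest bit score: with near-identical
    self-hits in training data, many grid points classify identical read
    sets, and the least stringent representative transfers best to
    references at other divergences.  The identity ceiling is relaxed
    before the bit score because any ceiling below 100 rejects exact
    matches outright.  The bit score, however, is never relaxed below the
    Karlin-Altschul noise floor (expected chance hits per read <= 0.01)
    when the database size is known: chance alignments concentrate just
    above the floor and inflate per-locus acceptance rates unevenly, which
    skews the constant calibration.  Families whose reads vanish in more
    than half the libraries at every grid point are flagged untrainable.
    """
    if not libs:
        raise ValueError("no aligned libraries")
    combos = np.array(grid.combinations(), dtype=float)
    # preference: coverage ascending, then pid descending, then bit ascending
    pref = np.lexsort((combos[:, 0], -combos[:, 2], combos[:, 1]))
    floor = 0.0
    if database_size_aa is not None:
        floor = noise_floor_bits(libs[0].read_length, database_size_aa)
    out: dict[str, MappingCutoffs] = {}
    untrainable: set[str] = set()
    for fi, fam in enumerate(family_names):
        err, zero_frac = _family_grid_errors(libs, fi, combos)
        med = np.median(err, axis=1)
        if not np.isfinite(med).any() or zero_frac.min() > 0.5:
            untrainable.add(fam)
            logger.warning("family %s untrainable on this grid", fam)
            pick = pref[0]
        else:
            best = float(np.nanmin(np.where(np.isfinite(med), med, np.nan)))
            row = err[int(np.argmin(np.where(np.isfinite(med), med, np.inf)))]
            finite = row[np.isfinite(row)]
            se = 1.2533 * finite.std() / max(np.sqrt(len(finite)), 1.0) if len(finite) else 0.0
            tol_ok = med <= best + se
            above_floor = tol_ok & (combos[:, 0] >= floor)
            candidates = above_floor if above_floor.any() else tol_ok
            pick = next(int(c) for c in pref if candidates[c])
        bs, cv, mp = combos[pick]
        out[fam] = MappingCutoffs(
            min_bit_score=float(bs),
            min_alignment_coverage=float(cv),
            max_percent_identity=float(mp),
        )
    return out, untrainable


def _counts_with_cutoffs(lib: AlignedLibrary, fam_idx: int, c: MappingCutoffs) -> int:
    sel = lib.top_family == fam_idx
    if not sel.any():
        return 0
    return int(
        (
            (lib.top_bit[sel] >= c.min_bit_score)
            & (lib.top_cov[sel] >= c.min_alignment_coverage)
            & (lib.top_pid[sel] <= c.max_percent_identity)
        ).sum()
    )


def fit_constants(
    libs: Sequence[AlignedLibrary],
    cutoffs: dict[str, MappingCutoffs],
    family_names: Sequence[str],
) -> dict[str, float]:
    """C per family: the median of true_AGS * R_j over libraries where the
    family mapped at least one read."""
    out = {}
    for fi, fam in enumerate(family_names):
        c_vals = []
        for lib in libs:
            n = _counts_with_cutoffs(lib, fi, cutoffs[fam])
            if n > 0:
                c_vals.append(lib.true_ags * n / lib.library_bp)
        if not c_vals:
            raise ValueError(f"family {fam!r}: no library mapped any read")
        if len(c_vals) < 10:
            logger.warning(
                "family %s: constant fitted from only %d libraries", fam, len(c_vals)
            )
        out[fam] = float(np.median(c_vals))
    return out


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u - css / (np.arange(len(v)) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def fit_weights(
    estimates: np.ndarray,  # (n_libraries, n_families), nan where unestimable
    truths: np.ndarray,
    max_evaluations: int = 5000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Simplex-constrained weights minimizing the median unsigned error of
    the weighted per-library estimate.  Derivative-free Nelder-Mead from the
    uniform start, with iterates projected onto the simplex."""
    n_lib, n_fam = estimates.shape
    finite = np.isfinite(estimates)
    est0 = np.where(finite, estimates, 0.0)

    def objective(w_raw: np.ndarray) -> float:
        w = _project_simplex(np.asarray(w_raw, dtype=float))
        num = est0 @ w
        den = finite @ w
        ok = den > 0
        if not ok.any():
            return np.inf
        err = np.abs(num[ok] / den[ok] - truths[ok]) / truths[ok]
        val = float(np.median(err))
        if not np.isfinite(val):
            raise ValueError("non-finite weight objective")
        return val

    uniform = np.full(n_fam, 1.0 / n_fam)
    f_uniform = objective(uniform)
    res = minimize(
        objective,
        uniform,
        method="Nelder-Mead",
        options={
            "maxfev": max_evaluations,
            "fatol": tol,
            "xatol": 1e-6,
            "disp": False,
        },
    )
    if res.fun > f_uniform - 1e-12:
        return uniform, float(f_uniform)
    w = _project_simplex(res.x)
    s = w.sum()
    if s <= 0:
        return uniform, float(f_uniform)
    return w / s, float(res.fun)


def train_model(
    genomes: Sequence[CommunityMember],
    db,
    read_lengths: Sequence[int] = (50, 100, 250, 500),
    coverage: float = 20.0,
    grid: CutoffGrid = CutoffGrid(),
    seed: int = 0,
) -> TrainedModel:
    """Full three-stage calibration.

    Each read length gets its own error-free single-genome libraries at the
    requested coverage, aligned once against the database; cutoffs,
    constants and weights are then fitted per length.
    """
    index = get_index(db)
    family_names = index.family_names
    entries: list[TrainedFamilyParams] = []
    for L in sorted(read_lengths):
        libs_raw = simulate_training_libraries(genomes, [L], coverage, seed=seed)
        libs = [align_library(lib, index) for lib in libs_raw]
        del libs_raw
        cutoffs, untrainable = optimize_cutoffs(
            libs, grid, family_names, database_size_aa=index.total_aa
        )
        constants = fit_constants(libs, cutoffs, family_names)
        est = np.full((len(libs), len(family_names)), np.nan)
        truths = np.array([lib.true_ags for lib in libs])
        for fi, fam in enumerate(family_names):
            for li, lib in enumerate(libs):
                n = _counts_with_cutoffs(lib, fi, cutoffs[fam])
                if n > 0:
                    est[li, fi] = constants[fam] * lib.library_bp / n
        weights, _obj = fit_weights(est, truths)
        for fi, fam in enumerate(family_names):
            entries.append(
                TrainedFamilyParams(
                    family_id=fam,
                    read_length=L,
                    cutoffs=cutoffs[fam],
                    proportionality_constant=constants[fam],
                    weight=float(weights[fi]),
                )
            )
    return TrainedModel(version_tag=getattr(db, "version_tag", "untagged"), entries=entries)


HOLDOUT_LEVELS = ("none", "species", "genus", "family", "order", "class", "phylum")


def excluded_sequences(db, community: CommunityProfile, level: str) -> list[str]:
    """Database sequence ids sharing any community member's taxon label at
    the given level ('none' excludes nothing)."""
    if level not in HOLDOUT_LEVELS:
        raise ValueError(f"unknown taxonomic level {level!r}")
    if level == "none":
        return []
    if db.taxonomy is None:
        raise ValueError("marker database carries no taxonomy labels")
    member_labels = set()
    for m in community.members:
        if m.taxonomy and level in m.taxonomy:
            member_labels.add(m.taxonomy[level])
    return [
        sid
        for sid, labels in db.taxonomy.items()
        if labels.get(level) in member_labels
    ]


def evaluate_holdout(
    model: TrainedModel,
    db,
    test_libraries: Sequence[tuple[CommunityProfile, Sequence[Read]]],
    level: str,
    cfg: PipelineConfig,
    hits_list: Sequence[HitTable] | None = None,
) -> list[dict]:
    """Estimate AGS for each test library with marker sequences from taxa
    matching the community excluded at the given level.

    Exclusion is applied by masking hits of a single search against the full
    database, which is equivalent to searching the reduced database since
    seeding and scoring are strictly per-target.  ``hits_list`` may carry
    precomputed searches of the trimmed libraries.
    """
    results = []
    index = get_index(db)
    for i, (community, reads) in enumerate(test_libraries):
        excl = excluded_sequences(db, community, level)
        emptied = []
        if excl:
            excl_set = set(excl)
            for fam in db.families:
                if all(sid in excl_set for sid, _ in fam.proteins):
                    emptied.append(fam.family_id)
        hits = hits_list[i] if hits_list is not None else None
        from .simulate import true_ags as _true_ags

        truth = _true_ags(community)
        res = estimate_ags(
            reads, index, model, cfg, hits=hits, exclude_seq_ids=excl
        )
        results.append(
            {
                "true_ags": truth,
                "estimated_ags": res.ags,
                "unsigned_error": unsigned_error(res.ags, truth),
                "signed_error": signed_error(res.ags, truth),
                "level": level,
                "n_excluded_sequences": len(excl),
                "emptied_families": emptied,
            }
        )
    return results
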