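"""The average-genome-size estimation pipeline.

Reads are quality-filtered, downsampled to the first n reads of at least i
bp, trimmed from the 3' end to exactly i bp, and searched against the marker
database.  A read maps to family j when its top-scoring alignment passes
that family's trained cutoffs (minimum bit score, minimum alignment
coverage, maximum percent identity) at read length i.  The relative
abundance R_j = mapped_reads_j / library bp then yields a per-family
estimate AGS_j = C_j / R_j through the trained proportionality constant;
outliers are removed and the surviving estimates are combined with trained
weights.  Genome equivalents are the full library's base count divided by
the AGS estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .align import HitTable, search_reads, top_hit
from .io import Read

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the estimation pipeline.

    ``n_reads``/``read_length`` define the downsample (first n reads of at
    least i bp, trimmed to i).  The three QC filters (duplicate removal,
    mean-quality, ambiguous-base) are off by default; the settings used for
    short-read human-microbiome data are dedupe on, min_mean_quality 5 and
    max_ambiguous_pct 5 at read length 70.
    """

    n_reads: int = 500_000
    read_length: int = 70
    dedupe: bool = False
    min_mean_quality: float | None = None
    max_ambiguous_pct: float | None = None
    min_classified_families: int = 3
    threads: int = 1

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        if self.read_length < 25:
            raise ValueError("read_length must be >= 25")


@dataclass(frozen=True)
class MappingCutoffs:
    min_bit_score: float
    min_alignment_coverage: float
    max_percent_identity: float

    def __post_init__(self) -> None:
        if self.min_bit_score < 0:
            raise ValueError("min_bit_score must be >= 0")
        if not 0 < self.min_alignment_coverage <= 1:
            raise ValueError("min_alignment_coverage must be in (0, 1]")
        if not 0 < self.max_percent_identity <= 100:
            raise ValueError("max_percent_identity must be in (0, 100]")


@dataclass(frozen=True)
class TrainedFamilyParams:
    family_id: str
    read_length: int
    cutoffs: MappingCutoffs
    proportionality_constant: float  # C in AGS = C / R
    weight: float

    def __post_init__(self) -> None:
        if self.proportionality_constant <= 0:
            raise ValueError("proportionality constant must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class TrainedModel:
    version_tag: str
    entries: list[TrainedFamilyParams]

    def __post_init__(self) -> None:
        by_len: dict[int, list[TrainedFamilyParams]] = {}
        for e in self.entries:
            by_len.setdefault(e.read_length, []).append(e)
        fams = None
        for length, group in by_len.items():
            w = sum(e.weight for e in group)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"weights at length {length} sum to {w}, expected 1")
            f = sorted(e.family_id for e in group)
            if fams is None:
                fams = f
            elif f != fams:
                raise ValueError("families differ between trained read lengths")
        self._by_len = {
            length: {e.family_id: e for e in group} for length, group in by_len.items()
        }

    @property
    def trained_lengths(self) -> list[int]:
        return sorted(self._by_len)

    @property
    def family_ids(self) -> list[str]:
        some = next(iter(self._by_len.values()))
        return sorted(some)

    def at_length(self, read_length: int) -> dict[str, TrainedFamilyParams]:
        return self._by_len[read_length]

    def dispatch_length(self, requested: int) -> int:
        """The trained length to use for a requested read length: exact if
        available, otherwise the largest trained length below it (never
        extrapolating upward)."""
        if requested in self._by_len:
            return requested
        below = [x for x in self.trained_lengths if x < requested]
        if not below:
            raise ValueError(
                f"no trained read length <= {requested} "
                f"(trained: {self.trained_lengths})"
            )
        chosen = max(below)
        logger.warning(
            "read length %d not trained; falling back to %d", requested, chosen
        )
        return chosen


@dataclass
class AgsResult:
    ags: float  # bp
    per_family: list[dict]  # family_id, mapped_reads, R_j, ags_j, outlier
    reads_used: int
    bases_used: int  # trimmed library bp used for R_j
    genome_equivalents: float
    library_bases_total: int  # full pre-QC base count
    read_length: int
    qc_report: dict = field(default_factory=dict)

    def n_families_used(self) -> int:
        return sum(
            1
            for row in self.per_family
            if row["ags_j"] is not None and not row["outlier"]
        )


@dataclass(frozen=True)
class RaesParams:
    """Constants of the closed-form marker-density estimator
    size = a + (b * L**-c) / x."""

    a: float = 21.2
    b: float = 4230.0
    c: float = 0.733

    def __post_init__(self) -> None:
        if self.b <= 0 or self.c <= 0:
            raise ValueError("b and c must be positive")


def qc_filter(reads: Sequence[Read], cfg: PipelineConfig) -> tuple[list[Read], dict]:
    """Duplicate, mean-quality, and ambiguous-base filters, in that order.

    Quality-based filters are skipped with a warning on FASTA input (reads
    without qualities).
    """
    report = {"input": len(reads), "duplicates": 0, "low_quality": 0, "ambiguous": 0}
    out: list[Read] = reads if isinstance(reads, list) else list(reads)
    if cfg.dedupe:
        seen: set[str] = set()
        kept = []
        for r in out:
            if r.seq in seen:
                report["duplicates"] += 1
            else:
                seen.add(r.seq)
                kept.append(r)
        out = kept
    if cfg.min_mean_quality is not None:
        if out and out[0].qual is None:
            logger.warning("FASTA input: mean-quality filter skipped")
        else:
            kept = []
            for r in out:
                mq = r.mean_quality()
                if mq is not None and mq < cfg.min_mean_quality:
                    report["low_quality"] += 1
                else:
                    kept.append(r)
            out = kept
    if cfg.max_ambiguous_pct is not None:
        kept = []
        thresh = cfg.max_ambiguous_pct / 100.0
        for r in out:
            n_bad = sum(1 for c in r.seq.upper() if c not in "ACGT")
            if len(r.seq) > 0 and n_bad / len(r.seq) > thresh:
                report["ambiguous"] += 1
            else:
                kept.append(r)
        out = kept
    report["output"] = len(out)
    return out, report


def downsample_and_trim(reads: Sequence[Read], n: int, i: int) -> list[Read]:
    """First n reads of at least i bp, each trimmed from the 3' end to i bp."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if i < 25:
        raise ValueError("read length must be >= 25")
    out = []
    for r in reads:
        if len(r.seq) >= i:
            out.append(Read(r.id, r.seq[:i], r.qual[:i] if r.qual else r.qual))
            if len(out) == n:
                break
    if not out:
        raise ValueError(f"no reads of length >= {i}")
    if len(out) < n:
        logger.info("only %d of the requested %d reads qualified", len(out), n)
    return out


def _cutoff_arrays(params: Mapping[str, TrainedFamilyParams], family_names: Sequence[str]):
    bs = np.empty(len(family_names))
    cv = np.empty(len(family_names))
    mp = np.empty(len(family_names))
    for i, fam in enumerate(family_names):
        if fam not in params:
            raise ValueError(f"family {fam!r} absent from trained model")
        c = params[fam].cutoffs
        bs[i] = c.min_bit_score
        cv[i] = c.min_alignment_coverage
        mp[i] = c.max_percent_identity
    return bs, cv, mp


def classify_reads(
    hits,
    model: TrainedModel,
    read_length: int,
    exclude_target_mask: np.ndarray | None = None,
) -> dict[str, int]:
    """Mapped-read counts per family.

    Each read contributes at most once: its top-scoring hit is taken, and
    the read maps to that hit's family iff bit >= min_bit_score AND coverage
    >= min_alignment_coverage AND identity <= max_percent_identity (all
    inclusive), using the family's cutoffs at the given trained read length.
    ``hits`` is a HitTable or a per-read sequence of AlignmentHit lists.
    """
    params = model.at_length(read_length)
    if isinstance(hits, HitTable):
        fam, bit, cov, pid = hits.top_hits(exclude_target_mask)
        names = hits.index.family_names
        bs, cv, mp = _cutoff_arrays(params, names)
        mapped = fam >= 0
        f = fam[mapped]
        ok = (bit[mapped] >= bs[f]) & (cov[mapped] >= cv[f]) & (pid[mapped] <= mp[f])
        counts = np.bincount(f[ok], minlength=len(names))
        out = {fam_id: 0 for fam_id in params}
        for i, name in enumerate(names):
            if name in out:
                out[name] += int(counts[i])
        return out
    counts_d = {fam_id: 0 for fam_id in params}
    for read_hits in hits:
        best = top_hit(read_hits)
        if best is None:
            continue
        if best.family_id not in params:
            raise ValueError(f"family {best.family_id!r} absent from trained model")
        c = params[best.family_id].cutoffs
        if (
            best.bit_score >= c.min_bit_score
            and best.alignment_coverage >= c.min_alignment_coverage
            and best.percent_identity <= c.max_percent_identity
        ):
            counts_d[best.family_id] += 1
    return counts_d


def family_relative_abundance(mapped_reads: int, library_size_bp: int) -> float:
    """R_j: reads mapped to the family per base pair of library searched."""
    if library_size_bp <= 0:
        raise ValueError("library size must be positive")
    return mapped_reads / library_size_bp


def family_ags_estimate(r_j: float, c_j: float) -> float | None:
    """AGS_j = C_j / R_j; None when the family mapped no reads."""
    if r_j < 0:
        raise ValueError("negative relative abundance")
    if r_j == 0:
        return None
    return c_j / r_j


def remove_outliers(
    estimates: Mapping[str, float], min_classified_families: int = 3
) -> dict[str, bool]:
    """Flag families whose estimate is more than 2-fold from the median of
    all estimates (|log2 ratio| > 1).  If flagging would leave fewer than
    the floor, the families closest to the median are retained."""
    if len(estimates) < min_classified_families:
        raise ValueError(
            f"only {len(estimates)} estimable families, need at least "
            f"{min_classified_families}"
        )
    fams = sorted(estimates)
    vals = np.array([estimates[f] for f in fams], dtype=float)
    med = float(np.median(vals))
    dist = np.abs(np.log2(vals / med))
    flagged = dist > 1.0
    n_keep = int((~flagged).sum())
    if n_keep < min_classified_families:
        order = np.argsort(dist, kind="stable")
        flagged = np.ones(len(fams), dtype=bool)
        flagged[order[:min_classified_families]] = False
    return {f: bool(flagged[i]) for i, f in enumerate(fams)}


def weighted_ags(
    estimates: Mapping[str, float], weights: Mapping[str, float]
) -> float:
    """Weight-renormalized average of the surviving per-family estimates."""
    if not estimates:
        raise ValueError("no estimates to average")
    fams = sorted(estimates)
    w = np.array([weights.get(f, 0.0) for f in fams], dtype=float)
    v = np.array([estimates[f] for f in fams], dtype=float)
    if w.sum() <= 0:
        logger.warning("surviving families all have zero weight; unweighted mean used")
        return float(v.mean())
    return float((w * v).sum() / w.sum())


def estimate_ags(
    reads: Sequence[Read],
    db,
    model: TrainedModel,
    cfg: PipelineConfig,
    hits: HitTable | None = None,
    exclude_seq_ids: Sequence[str] | None = None,
    library_bases_total: int | None = None,
) -> AgsResult:
    """Run the full pipeline on a read library.

    ``hits`` may carry a precomputed search of the trimmed, downsampled reads
    (the caller is responsible for the correspondence); ``exclude_seq_ids``
    removes database sequences from consideration, equivalent to searching a
    database without them.
    """
    from .align import get_index

    if library_bases_total is None:
        library_bases_total = sum(len(r.seq) for r in reads)
    filtered, report = qc_filter(reads, cfg)
    trimmed = downsample_and_trim(filtered, cfg.n_reads, cfg.read_length)
    if len(trimmed) < 300_000:
        logger.info(
            "%d reads used; estimates stabilize around 300k reads", len(trimmed)
        )
    length = model.dispatch_length(cfg.read_length)
    if hits is None:
        hits = search_reads(trimmed, db)
    mask = None
    if exclude_seq_ids:
        mask = hits.index.excluded_target_mask(exclude_seq_ids)
    counts = classify_reads(hits, model, length, exclude_target_mask=mask)
    n_used = len(trimmed)
    library_bp = n_used * cfg.read_length
    params = model.at_length(length)
    r_j = {f: family_relative_abundance(c, library_bp) for f, c in counts.items()}
    est = {}
    for f, r in r_j.items():
        e = family_ags_estimate(r, params[f].proportionality_constant)
        if e is not None:
            est[f] = e
    flags = remove_outliers(est, cfg.min_classified_families)
    survivors = {f: v for f, v in est.items() if not flags[f]}
    weights = {f: params[f].weight for f in survivors}
    ags = weighted_ags(survivors, weights)
    per_family = []
    for f in sorted(params):
        per_family.append(
            {
                "family_id": f,
                "mapped_reads": counts[f],
                "R_j": r_j[f],
                "ags_j": est.get(f),
                "outlier": flags.get(f, False) if f in est else False,
            }
        )
    return AgsResult(
        ags=ags,
        per_family=per_family,
        reads_used=n_used,
        bases_used=library_bp,
        genome_equivalents=genome_equivalents(library_bases_total, ags),
        library_bases_total=library_bases_total,
        read_length=length,
        qc_report=report,
    )


def genome_equivalents(library_size_bp: float, ags: float) -> float:
    """Library size (bp) / AGS (bp): the number of average genomes' worth of
    sequence in the library.  The library size is the full library's base
    count, since it normalizes whole-library gene counts."""
    if library_size_bp <= 0 or ags <= 0:
        raise ValueError("library size and AGS must be positive")
    return library_size_bp / ags


def bootstrap_dispersion(
    reads: Sequence[Read],
    estimator: Callable[[Sequence[Read]], float],
    sample_sizes: Sequence[int],
    iterations: int = 100,
    seed: int = 0,
) -> dict[int, dict]:
    """Dispersion (variance/mean) of repeated AGS estimates at each sample
    size, drawing reads uniformly without replacement.

    ``estimator`` maps a list of reads to an AGS value (see
    :func:`make_estimator`); iterations that fail (e.g. too few classified
    families) are recorded as missing.
    """
    if iterations < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    reads = list(reads)
    out: dict[int, dict] = {}
    for size in sample_sizes:
        if size > len(reads):
            raise ValueError(f"sample size {size} exceeds library ({len(reads)})")
        rng = np.random.default_rng([int(seed), 97, int(size)])
        values = []
        missing = 0
        for _ in range(iterations):
            idx = rng.choice(len(reads), size=size, replace=False)
            try:
                values.append(estimator([reads[i] for i in idx]))
            except ValueError:
                missing += 1
        if values:
            arr = np.array(values)
            dispersion = float(arr.var() / arr.mean()) if arr.mean() != 0 else 0.0
        else:
            dispersion = math.nan
        out[size] = {
            "dispersion": dispersion,
            "n": len(values),
            "missing": missing,
            "mean": float(np.mean(values)) if values else math.nan,
        }
    return out


def make_estimator(db, model: TrainedModel, cfg: PipelineConfig):
    """An estimator closure over a fixed database/model for bootstrapping."""

    def _est(subset: Sequence[Read]) -> float:
        sub_cfg = PipelineConfig(
            n_reads=max(len(subset), 1),
            read_length=cfg.read_length,
            dedupe=cfg.dedupe,
            min_mean_quality=cfg.min_mean_quality,
            max_ambiguous_pct=cfg.max_ambiguous_pct,
            min_classified_families=cfg.min_classified_families,
        )
        return estimate_ags(subset, db, model, sub_cfg).ags

    return _est


def raes_estimate(
    marker_density: float, read_length: float, params: RaesParams = RaesParams()
) -> float:
    """Closed-form comparator: size = a + (b * L**-c) / x with x the marker
    hits per megabase.  Returned on the formula's own (unit-ambiguous) scale."""
    if marker_density <= 0:
        raise ValueError("marker density must be positive")
    if read_length <= 0:
        raise ValueError("read length must be positive")
    return params.a + (params.b * read_length ** (-params.c)) / marker_density
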