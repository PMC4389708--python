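"""Gene-family abundance normalization.

RPKG (reads per kilobase per genome equivalent) divides length-normalized
read counts by the number of genome equivalents in the library
(library bp / AGS), so that for well-sampled genes it approximates the
average copy number per cell.  Rescaling RPKG values to sum to one makes AGS
and library size cancel, recovering the ordinary relative-abundance metric —
an identity this module preserves exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneCountRow:
    gene_family_id: str
    mapped_reads: int
    gene_length_kb: float

    def __post_init__(self) -> None:
        if self.mapped_reads < 0:
            raise ValueError("mapped_reads must be >= 0")
        if self.gene_length_kb <= 0:
            raise ValueError("gene_length_kb must be positive")


@dataclass
class GeneCountTable:
    rows: list[GeneCountRow]
    library_size_bp: float
    ags_bp: float | None = None

    def __post_init__(self) -> None:
        if self.library_size_bp <= 0:
            raise ValueError("library_size_bp must be positive")

    def length_normalized(self) -> np.ndarray:
        return np.array([r.mapped_reads / r.gene_length_kb for r in self.rows])


@dataclass(frozen=True)
class AbundanceRecord:
    gene_family_id: str
    rpkg: float | None
    relative_abundance: float


def compute_rpkg(table: GeneCountTable) -> list[AbundanceRecord]:
    """RPKG = (mapped reads / gene length in kb) / genome equivalents, with
    genome equivalents = library bp / AGS bp."""
    if table.ags_bp is None or table.ags_bp <= 0:
        raise ValueError("AGS required (and positive) to compute RPKG")
    genome_eq = table.library_size_bp / table.ags_bp
    norm = table.length_normalized()
    rel = _relative(norm)
    return [
        AbundanceRecord(r.gene_family_id, float(n / genome_eq), float(rel[i]))
        for i, (r, n) in enumerate(zip(table.rows, norm))
    ]


def _relative(norm: np.ndarray) -> np.ndarray:
    total = norm.sum()
    if total == 0:
        logger.warning("no mapped reads in table; relative abundances are zero")
        return np.zeros_like(norm)
    return norm / total


def compute_relative_abundance(table: GeneCountTable) -> list[AbundanceRecord]:
    """Length-normalized counts rescaled to sum to one (RPKG left unset)."""
    if not table.rows:
        raise ValueError("empty gene count table")
    rel = _relative(table.length_normalized())
    return [
        AbundanceRecord(r.gene_family_id, None, float(rel[i]))
        for i, r in enumerate(table.rows)
    ]


def single_copy_cv(
    samples: Mapping[str, Sequence[AbundanceRecord]],
    essential_family_ids: Sequence[str],
    metric: str = "rpkg",
) -> tuple[float, list[str]]:
    """Coefficient of variation of essential single-copy gene abundance
    across samples.

    For each sample the median abundance over the essential families is
    collected; returned is the CV (population sd / mean) of those per-sample
    medians, plus the families absent from every sample.  Essential
    single-copy genes are a priori present at one copy per cell, so a good
    normalization yields low CV.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    essential = set(essential_family_ids)
    seen: set[str] = set()
    per_sample_medians = []
    for name in sorted(samples):
        vals = []
        for rec in samples[name]:
            if rec.gene_family_id in essential:
                seen.add(rec.gene_family_id)
                v = rec.rpkg if metric == "rpkg" else rec.relative_abundance
                if v is None:
                    raise ValueError(f"sample {name!r} lacks {metric} values")
                vals.append(v)
        if not vals:
            raise ValueError(f"sample {name!r} has no essential families")
        per_sample_medians.append(float(np.median(vals)))
    absent = sorted(essential - seen)
    arr = np.array(per_sample_medians)
    mean = arr.mean()
    if mean == 0:
        return 0.0, absent
    return float(arr.std() / mean), absent


def read_gene_counts(path, library_size_bp: float, ags_bp: float | None = None) -> GeneCountTable:
    """Read a `gene_family_id<TAB>mapped_reads<TAB>gene_length_kb` table."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0] == "gene_family_id":
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            rows.append(GeneCountRow(parts[0], int(parts[1]), float(parts[2])))
    return GeneCountTable(rows, library_size_bp=library_size_bp, ags_bp=ags_bp)


def write_abundance(records: Sequence[AbundanceRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_family_id\trpkg\trelative_abundance\n")
        for r in records:
            rpkg = "NA" if r.rpkg is None else f"{r.rpkg:.8g}"
            fh.write(f"{r.gene_family_id}\t{rpkg}\t{r.relative_abundance:.8g}\n")
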