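"""Essential single-copy marker gene families and their protein database.

A marker database groups reference protein sequences into families that are
expected to occur exactly once in (nearly) every bacterial and archaeal
genome.  Because every cell contributes one copy of each family, the rate at
which a shotgun library samples a family is inversely proportional to the
community's average genome size — the property the whole estimator rests on.

This module loads and validates such databases.  Validation searches each
candidate family against complete proteomes and keeps families that are
universal (present in ~all genomes), single copy on average, and stable
(copy-number variance near zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import numpy as np

_AA_OK = set("ARNDCQEGHILKMFPSTWYVX")


@dataclass
class MarkerFamily:
    """One marker family: its reference proteins and a representative length
    (the median protein length, in residues)."""

    family_id: str
    proteins: list[tuple[str, str]]
    representative_length: float = 0.0

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"family {self.family_id!r} has no proteins")
        for seq_id, seq in self.proteins:
            if not seq:
                raise ValueError(f"empty sequence {seq_id!r} in family {self.family_id!r}")
            bad = set(seq.upper()) - _AA_OK
            if bad:
                raise ValueError(
                    f"sequence {seq_id!r} contains non-amino-acid letters: {sorted(bad)}"
                )
        if not self.representative_length:
            self.representative_length = float(median(len(s) for _, s in self.proteins))
        if self.representative_length <= 0:
            raise ValueError("representative_length must be positive")


@dataclass
class MarkerDatabase:
    families: list[MarkerFamily]
    version_tag: str = "untagged"
    # optional per-sequence taxonomy: seq_id -> {level: label}
    taxonomy: dict[str, dict[str, str]] | None = None

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("marker database needs at least one family")
        seen: set[str] = set()
        fams: set[str] = set()
        for fam in self.families:
            if fam.family_id in fams:
                raise ValueError(f"duplicate family_id {fam.family_id!r}")
            fams.add(fam.family_id)
            for seq_id, _ in fam.proteins:
                if seq_id in seen:
                    raise ValueError(f"duplicate sequence_id {seq_id!r}")
                seen.add(seq_id)

    @property
    def family_ids(self) -> list[str]:
        return [f.family_id for f in self.families]

    @property
    def n_proteins(self) -> int:
        return sum(len(f.proteins) for f in self.families)

    def family(self, family_id: str) -> MarkerFamily:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)

    def representative_lengths(self) -> dict[str, float]:
        return {f.family_id: f.representative_length for f in self.families}

    def subset_sequences(self, exclude_seq_ids: Iterable[str]) -> "MarkerDatabase":
        """A copy with the given sequences removed (families left empty are
        dropped)."""
        excl = set(exclude_seq_ids)
        fams = []
        for f in self.families:
            keep = [(sid, s) for sid, s in f.proteins if sid not in excl]
            if keep:
                fams.append(MarkerFamily(f.family_id, keep))
        if not fams:
            raise ValueError("exclusion removed every sequence in the database")
        tax = None
        if self.taxonomy is not None:
            tax = {sid: lab for sid, lab in self.taxonomy.items() if sid not in excl}
        return MarkerDatabase(fams, version_tag=self.version_tag, taxonomy=tax)


@dataclass(frozen=True)
class ValidationConfig:
    """Presence thresholds: a family member is present in a genome when some
    proteome protein aligns to it with E-value below ``max_evalue`` and both
    sequences covered by at least ``min_bidirectional_coverage`` of their
    length."""

    max_evalue: float = 1e-5
    min_bidirectional_coverage: float = 0.70

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if not 0 < self.min_bidirectional_coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")


@dataclass(frozen=True)
class FamilyValidationStats:
    family_id: str
    universality: float
    mean_copy_number: float
    copy_number_variance: float

    def __post_init__(self) -> None:
        if not 0 <= self.universality <= 1:
            raise ValueError("universality out of [0, 1]")
        if self.mean_copy_number < 0 or self.copy_number_variance < 0:
            raise ValueError("negative copy-number statistics")


def demo_database(n_families: int = 5, protein_length: int = 120, seed: int = 0) -> MarkerDatabase:
    """A tiny synthetically generated marker set for demonstrations and
    tests.  Real marker sets (e.g. the universal single-copy ribosomal
    families) are loaded from user-supplied FASTA with
    :func:`load_marker_database`."""
    from .simulate import SyntheticMarkerSpec, generate_marker_families

    return generate_marker_families(
        SyntheticMarkerSpec(
            n_families=n_families, ancestral_protein_length=protein_length, seed=seed
        )
    )


def load_marker_database(fasta_path, metadata_path, version_tag: str = "user") -> MarkerDatabase:
    """Load a protein FASTA plus a `sequence_id<TAB>family_id` metadata table.

    Every FASTA record must have a family assignment; records are grouped by
    family and the representative length is the per-family median protein
    length.
    """
    from Bio import SeqIO

    mapping: dict[str, str] = {}
    with open(metadata_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{metadata_path}:{ln}: expected two tab-separated columns")
            if ln == 1 and parts[0] == "sequence_id":
                continue
            mapping[parts[0]] = parts[1]
    groups: dict[str, list[tuple[str, str]]] = {}
    n_records = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_records += 1
        fam = mapping.get(rec.id)
        if fam is None:
            raise ValueError(f"sequence {rec.id!r} has no family assignment in metadata")
        groups.setdefault(fam, []).append((rec.id, str(rec.seq).upper()))
    if n_records == 0:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    families = [MarkerFamily(fam, prots) for fam, prots in sorted(groups.items())]
    return MarkerDatabase(families, version_tag=version_tag)


def validate_marker_set(
    db: MarkerDatabase,
    proteomes: Sequence[tuple[str, Sequence[str]]],
    cfg: ValidationConfig = ValidationConfig(),
) -> list[FamilyValidationStats]:
    """Copy-number statistics of every family across complete proteomes.

    A proteome protein counts as one copy of a family if it aligns to any
    member of the family with E-value below the threshold and bidirectional
    coverage (both query and target spanning >= the configured fraction of
    their own length); each protein counts at most once per family.
    """
    from .align import get_index, search_proteins

    if not proteomes:
        raise ValueError("no proteomes supplied")
    index = get_index(db)
    fam_ids = index.family_names
    counts = np.zeros((len(proteomes), len(fam_ids)), dtype=np.int64)
    tlens = np.array([index.t_off[i + 1] - index.t_off[i] for i in range(index.n_targets)])
    for gi, (_genome_id, prots) in enumerate(proteomes):
        queries = [(f"p{gi}_{pi}", seq) for pi, seq in enumerate(prots)]
        hits = search_proteins(queries, index, min_bit=5.0)
        qlen = hits.read_length[hits.read_idx]
        qcov = (hits.qend - hits.qstart + 1) / qlen
        tcov = (hits.tend - hits.tstart + 1) / tlens[hits.target_idx]
        ok = (
            (hits.evalue < cfg.max_evalue)
            & (qcov >= cfg.min_bidirectional_coverage)
            & (tcov >= cfg.min_bidirectional_coverage)
        )
        fam_of_hit = index.family_idx[hits.target_idx[ok]]
        # one count per (protein, family), regardless of how many members hit
        pairs = np.unique(hits.read_idx[ok] * len(fam_ids) + fam_of_hit)
        for p in pairs:
            counts[gi, p % len(fam_ids)] += 1
    stats = []
    for fi, fam in enumerate(fam_ids):
        col = counts[:, fi]
        stats.append(
            FamilyValidationStats(
                family_id=fam,
                universality=float(np.mean(col >= 1)),
                mean_copy_number=float(np.mean(col)),
                copy_number_variance=float(np.var(col)),
            )
        )
    return stats


def select_families(
    stats: Sequence[FamilyValidationStats],
    min_universality: float = 0.95,
    max_copy_deviation: float = 0.05,
    max_variance: float = 0.05,
) -> list[str]:
    """Families passing all three single-copy filters, sorted by id."""
    if not 0 <= min_universality <= 1:
        raise ValueError("min_universality out of range")
    if max_copy_deviation < 0 or max_variance < 0:
        raise ValueError("thresholds must be non-negative")
    chosen = [
        s.family_id
        for s in stats
        if s.universality >= min_universality
        and abs(s.mean_copy_number - 1.0) <= max_copy_deviation
        and s.copy_number_variance <= max_variance
    ]
    return sorted(set(chosen))


def write_validation_report(stats: Sequence[FamilyValidationStats], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tuniversality\tmean_copy_number\tcopy_number_variance\n")
        for s in stats:
            fh.write(
                f"{s.family_id}\t{s.universality:.6g}\t{s.mean_copy_number:.6g}"
                f"\t{s.copy_number_variance:.6g}\n"
            )
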