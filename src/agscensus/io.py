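"""Sequence and model I/O: streaming FASTA/FASTQ readers (plain or gzip),
FASTQ/truth writers for the simulator, and TrainedModel (de)serialization.
"""

from __future__ import annotations

import gzip
import io as _io
import json
import warnings
from pathlib import Path
from typing import Iterator, NamedTuple

PHRED_OFFSET = 33


class Read(NamedTuple):
    """A sequencing read; ``qual`` is the Phred+33 quality string or None for
    FASTA input."""

    id: str
    seq: str
    qual: str | None = None

    def mean_quality(self) -> float | None:
        if self.qual is None or not self.qual:
            return None
        return sum(ord(c) - PHRED_OFFSET for c in self.qual) / len(self.qual)


def _open_text(path):
    path = Path(path)
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.GzipFile(fileobj=fh), encoding="ascii")
    return _io.TextIOWrapper(fh, encoding="ascii")


def sniff_format(path) -> str:
    """'fasta' or 'fastq', decided from the first non-blank character."""
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                return "fasta"
            if line.startswith("@"):
                return "fastq"
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {line[:1]!r})")
    raise ValueError(f"{path}: empty file")


def read_sequences(path) -> Iterator[Read]:
    """Stream reads from FASTA or FASTQ (gzip auto-detected, CRLF tolerated).

    FASTQ qualities are kept as Phred+33 strings.  Malformed or truncated
    records raise ValueError naming the offending record.
    """
    fmt = sniff_format(path)
    with _open_text(path) as fh:
        if fmt == "fasta":
            name = None
            chunks: list[str] = []
            for line in fh:
                line = line.rstrip("\r\n")
                if line.startswith(">"):
                    if name is not None:
                        yield Read(name, "".join(chunks))
                    name = line[1:].split()[0] if len(line) > 1 else ""
                    chunks = []
                elif line:
                    chunks.append(line)
            if name is not None:
                if not chunks:
                    raise ValueError(f"{path}: record {name!r} has no sequence")
                yield Read(name, "".join(chunks))
        else:
            lineno = 0
            while True:
                rec = []
                for _ in range(4):
                    line = fh.readline()
                    lineno += 1
                    if not line:
                        break
                    rec.append(line.rstrip("\r\n"))
                if not rec:
                    break
                if len(rec) < 4:
                    raise ValueError(
                        f"{path}: truncated FASTQ record near line {lineno} ({rec[0][:40]!r})"
                    )
                hdr, seq, plus, qual = rec
                if not hdr.startswith("@") or not plus.startswith("+"):
                    raise ValueError(f"{path}: malformed FASTQ record at line {lineno - 3}")
                if len(seq) != len(qual):
                    raise ValueError(
                        f"{path}: quality length mismatch for record {hdr[1:].split()[0]!r}"
                    )
                yield Read(hdr[1:].split()[0], seq, qual)


def write_fastq(reads, path, gzip_output: bool | None = None) -> None:
    path = Path(path)
    if gzip_output is None:
        gzip_output = path.suffix == ".gz"
    opener = gzip.open if gzip_output else open
    with opener(path, "wt") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_truth(truth: dict, tsv_path, json_path=None) -> None:
    """Write the simulator's truth record: per-genome TSV plus a JSON header
    carrying the true AGS, seed, and config."""
    with open(tsv_path, "w") as fh:
        fh.write("genome_id\tsize_bp\trel_abund\tn_reads\tcarries_markers\n")
        for row in truth["members"]:
            fh.write(
                f"{row['genome_id']}\t{row['size_bp']}\t{row['rel_abund']:.8g}"
                f"\t{row['n_reads']}\t{int(row['carries_markers'])}\n"
            )
    if json_path is not None:
        head = {k: v for k, v in truth.items() if k != "members"}
        with open(json_path, "w") as fh:
            json.dump(head, fh, indent=1)


def write_ags_result(result, path, fmt: str = "tsv") -> None:
    """Write an AgsResult: summary line plus a per-family block (TSV), or the
    same structure as JSON."""
    if fmt == "json":
        payload = {
            "average_genome_size_bp": result.ags,
            "genome_equivalents": result.genome_equivalents,
            "reads_used": result.reads_used,
            "bases_used": result.bases_used,
            "library_bases_total": result.library_bases_total,
            "read_length": result.read_length,
            "n_families_used": result.n_families_used(),
            "qc_report": result.qc_report,
            "per_family": result.per_family,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    with open(path, "w") as fh:
        fh.write(
            "average_genome_size_bp\tgenome_equivalents\treads_used\tbases_used"
            "\tn_families_used\n"
        )
        fh.write(
            f"{result.ags:.2f}\t{result.genome_equivalents:.4f}\t{result.reads_used}"
            f"\t{result.bases_used}\t{result.n_families_used()}\n"
        )
        fh.write("family_id\tmapped_reads\tR_j\tags_j\toutlier\n")
        for row in result.per_family:
            ags_j = "NA" if row["ags_j"] is None else f"{row['ags_j']:.2f}"
            fh.write(
                f"{row['family_id']}\t{row['mapped_reads']}\t{row['R_j']:.6g}"
                f"\t{ags_j}\t{int(row['outlier'])}\n"
            )


def save_model(model, path) -> None:
    """Serialize a TrainedModel to JSON (bit-exact round trip)."""
    payload = {
        "format": "agscensus-model-v1",
        "version_tag": model.version_tag,
        "trained_lengths": list(model.trained_lengths),
        "entries": [
            {
                "family_id": e.family_id,
                "read_length": e.read_length,
                "min_bit_score": e.cutoffs.min_bit_score,
                "min_alignment_coverage": e.cutoffs.min_alignment_coverage,
                "max_percent_identity": e.cutoffs.max_percent_identity,
                "C": e.proportionality_constant,
                "weight": e.weight,
            }
            for e in model.entries
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def save_model_tsv(model, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "family_id\tread_length\tmin_bit_score\tmin_alignment_coverage"
            "\tmax_percent_identity\tC\tweight\n"
        )
        for e in model.entries:
            fh.write(
                f"{e.family_id}\t{e.read_length}\t{e.cutoffs.min_bit_score!r}"
                f"\t{e.cutoffs.min_alignment_coverage!r}\t{e.cutoffs.max_percent_identity!r}"
                f"\t{e.proportionality_constant!r}\t{e.weight!r}\n"
            )


def load_model(path, expected_version_tag: str | None = None, force: bool = False):
    """Load a TrainedModel from JSON (or legacy flat TSV, with a warning)."""
    from .ags_core import MappingCutoffs, TrainedFamilyParams, TrainedModel

    path = Path(path)
    entries = []
    version_tag = "untagged"
    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == "{":
            payload = json.load(fh)
            version_tag = payload.get("version_tag", "untagged")
            rows = payload["entries"]
        else:
            warnings.warn(f"{path}: legacy flat-TSV model format", stacklevel=2)
            rows = []
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    for row in rows:
        entries.append(
            TrainedFamilyParams(
                family_id=row["family_id"],
                read_length=int(row["read_length"]),
                cutoffs=MappingCutoffs(
                    min_bit_score=float(row["min_bit_score"]),
                    min_alignment_coverage=float(row["min_alignment_coverage"]),
                    max_percent_identity=float(row["max_percent_identity"]),
                ),
                proportionality_constant=float(row.get("C", row.get("proportionality_constant"))),
                weight=float(row["weight"]),
            )
        )
    model = TrainedModel(version_tag=version_tag, entries=entries)
    if expected_version_tag is not None and version_tag != expected_version_tag:
        msg = (
            f"model version_tag {version_tag!r} does not match marker database "
            f"{expected_version_tag!r}"
        )
        if force:
            warnings.warn(msg + " (--force given)", stacklevel=2)
        else:
            raise ValueError(msg)
    return model
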