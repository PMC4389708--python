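"""Translated homology search of nucleotide reads against a protein marker
database.

The engine is a k-mer-seeded Smith-Waterman: each read is translated in all
six frames, 5-mer amino-acid seeds are looked up in a direct-address index of
the database, and every (read, frame, target) pair with two seeds on one
diagonal (one seed for very short peptides) is extended with a banded affine
Smith-Waterman around the seed diagonals.  Scores are converted to bit scores
with Karlin-Altschul statistics, ``bit = (lambda * S - ln K) / ln 2``, and
E-values as ``E = m * n * 2**-bit`` with m the translated read length and n
the database size in residues.

An external translated search can be substituted by importing its tabular
hits with :func:`read_external_hits`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _codec
from ._codec import AA_X, codon_table, encode_dna, load_matrix, revcomp_codes
from ._sw import banded_sw_batch, scan_candidates

FRAME_LABELS = (1, 2, 3, -1, -2, -3)
_KMER_K = 5
_KMER_BASE = 24
_KMER_SPACE = _KMER_BASE**_KMER_K
# frames with fewer available k-mers than this only need a single seed hit
_TWO_HIT_MIN_KMERS = 8


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: substitution matrix, affine gaps, and the
    Karlin-Altschul parameters used for bit scores and E-values.

    Defaults are the conventional BLOSUM62 / gap 11,1 constants
    (lambda = 0.267, K = 0.041).  ``database_size`` (residues) defaults to
    the size of the database being searched.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    k: float = 0.041
    database_size: int | None = None

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")

    def bit_score(self, raw: float) -> float:
        return (self.lambda_ * raw - math.log(self.k)) / math.log(2)


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    family_id: str
    target_sequence_id: str
    bit_score: float
    percent_identity: float
    alignment_coverage: float
    e_value: float
    frame: int
    query_span: tuple[int, int] = (0, 0)  # 0-based inclusive, peptide coords
    target_span: tuple[int, int] = (0, 0)


class PeptideIndex:
    """Direct-address 5-mer index over the proteins of a marker database."""

    def __init__(self, db, k: int = _KMER_K):
        self.db = db
        self.k = k
        seq_ids: list[str] = []
        family_ids: list[str] = []
        codes_list: list[np.ndarray] = []
        for fam in db.families:
            for seq_id, seq in fam.proteins:
                seq_ids.append(seq_id)
                family_ids.append(fam.family_id)
                codes_list.append(_codec.encode_aa(seq))
        if not seq_ids:
            raise ValueError("marker database contains no protein sequences")
        self.seq_ids = seq_ids
        self.family_ids = family_ids
        fams = sorted({f.family_id for f in db.families})
        self.family_names = fams
        fam_lookup = {f: i for i, f in enumerate(fams)}
        self.family_idx = np.array(
            [fam_lookup[f] for f in family_ids], dtype=np.int32
        )
        # lexicographic rank of target seq_ids, for deterministic tie-breaks
        order = sorted(range(len(seq_ids)), key=lambda i: seq_ids[i])
        self.seqid_rank = np.empty(len(seq_ids), dtype=np.int32)
        for r, i in enumerate(order):
            self.seqid_rank[i] = r
        self.t_off = np.zeros(len(codes_list) + 1, dtype=np.int64)
        for i, c in enumerate(codes_list):
            self.t_off[i + 1] = self.t_off[i] + len(c)
        self.t_flat = np.concatenate(codes_list).astype(np.int8)
        self.total_aa = int(self.t_off[-1])
        self.max_tlen = int(np.max(np.diff(self.t_off)))
        self.n_targets = len(seq_ids)
        self._build_kmer_index(codes_list)

    def _build_kmer_index(self, codes_list: list[np.ndarray]) -> None:
        k = self.k
        all_codes = []
        all_target = []
        all_pos = []
        for t, c in enumerate(codes_list):
            if len(c) < k:
                continue
            kc, valid = _kmer_codes(c[np.newaxis, :], k)
            pos = np.nonzero(valid[0])[0]
            all_codes.append(kc[0][valid[0]])
            all_target.append(np.full(len(pos), t, dtype=np.int32))
            all_pos.append(pos.astype(np.int32))
        codes = np.concatenate(all_codes) if all_codes else np.empty(0, np.int64)
        self.kcount = np.bincount(codes, minlength=_KMER_SPACE).astype(np.int32)
        self.kstart = np.zeros(_KMER_SPACE + 1, dtype=np.int64)
        np.cumsum(self.kcount, out=self.kstart[1:])
        order = np.argsort(codes, kind="stable")
        self.p_target = np.concatenate(all_target)[order] if all_codes else np.empty(0, np.int32)
        self.p_pos = np.concatenate(all_pos)[order] if all_codes else np.empty(0, np.int32)

    def excluded_target_mask(self, exclude_seq_ids: Iterable[str]) -> np.ndarray:
        excl = set(exclude_seq_ids)
        return np.array([s in excl for s in self.seq_ids], dtype=bool)


def _kmer_codes(pep: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling base-24 k-mer codes over a peptide code matrix (n, p).

    Returns (codes (n, p-k+1), valid mask) where windows containing X or a
    stop are invalid.
    """
    n, p = pep.shape
    nk = p - k + 1
    if nk <= 0:
        return np.empty((n, 0), np.int64), np.empty((n, 0), bool)
    codes = np.zeros((n, nk), dtype=np.int64)
    valid = np.ones((n, nk), dtype=bool)
    for j in range(k):
        win = pep[:, j : j + nk]
        codes *= _KMER_BASE
        codes += win
        valid &= win < AA_X
    codes[~valid] = 0
    return codes, valid


@dataclass
class HitTable:
    """Columnar batch of alignment hits against one PeptideIndex."""

    index: PeptideIndex
    scoring: ScoringScheme
    read_ids: list[str]
    read_length: np.ndarray  # nt length per read (or aa length in protein mode)
    read_idx: np.ndarray
    target_idx: np.ndarray
    frame_idx: np.ndarray  # 0..5 into FRAME_LABELS; 0 in protein mode
    bit: np.ndarray
    evalue: np.ndarray
    coverage: np.ndarray
    pid: np.ndarray
    qstart: np.ndarray
    qend: np.ndarray
    tstart: np.ndarray
    tend: np.ndarray
    protein_mode: bool = False

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    def top_hits(self, exclude_target_mask: np.ndarray | None = None):
        """Per-read top-scoring hit.

        Ties on bit score are broken by lower E-value, then lexicographic
        target sequence id.  Returns (family_idx, bit, coverage, pid) arrays
        of length n_reads; family_idx is -1 for reads without hits.
        """
        keep = np.ones(len(self.read_idx), dtype=bool)
        if exclude_target_mask is not None:
            keep &= ~exclude_target_mask[self.target_idx]
        ri = self.read_idx[keep]
        fam = np.full(self.n_reads, -1, dtype=np.int32)
        bit = np.zeros(self.n_reads, dtype=np.float64)
        cov = np.zeros(self.n_reads, dtype=np.float64)
        pid = np.zeros(self.n_reads, dtype=np.float64)
        if len(ri) == 0:
            return fam, bit, cov, pid
        rank = self.index.seqid_rank[self.target_idx[keep]]
        order = np.lexsort((rank, self.evalue[keep], -self.bit[keep], ri))
        first = np.unique(ri[order], return_index=True)[1]
        sel = order[first]
        rsel = ri[sel]
        fam[rsel] = self.index.family_idx[self.target_idx[keep][sel]]
        bit[rsel] = self.bit[keep][sel]
        cov[rsel] = self.coverage[keep][sel]
        pid[rsel] = self.pid[keep][sel]
        return fam, bit, cov, pid

    def to_hit_lists(self) -> list[list[AlignmentHit]]:
        """Expand into per-read lists of AlignmentHit (small scale only)."""
        out: list[list[AlignmentHit]] = [[] for _ in range(self.n_reads)]
        for h in range(len(self.read_idx)):
            r = int(self.read_idx[h])
            t = int(self.target_idx[h])
            out[r].append(
                AlignmentHit(
                    read_id=self.read_ids[r],
                    family_id=self.index.family_ids[t],
                    target_sequence_id=self.index.seq_ids[t],
                    bit_score=float(self.bit[h]),
                    percent_identity=float(self.pid[h]),
                    alignment_coverage=float(self.coverage[h]),
                    e_value=float(self.evalue[h]),
                    frame=0 if self.protein_mode else FRAME_LABELS[self.frame_idx[h]],
                    query_span=(int(self.qstart[h]), int(self.qend[h])),
                    target_span=(int(self.tstart[h]), int(self.tend[h])),
                )
            )
        for hits in out:
            hits.sort(key=lambda h: (-h.bit_score, h.e_value, h.target_sequence_id))
        return out


def six_frame_translate(dna: str) -> list[str]:
    """Translate a DNA sequence in all six frames (+1,+2,+3,-1,-2,-3).

    Codons containing an ambiguous base give X; stop codons give '*';
    trailing partial codons are dropped.
    """
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    table = codon_table()
    fwd = encode_dna(dna)
    rev = revcomp_codes(fwd)
    peptides = []
    for strand in (fwd, rev):
        for off in range(3):
            n = (len(strand) - off) // 3
            cod = strand[off : off + 3 * n].reshape(n, 3).astype(np.int64)
            aa = table[cod[:, 0] * 25 + cod[:, 1] * 5 + cod[:, 2]]
            peptides.append(_codec.decode_aa(aa))
    return peptides


def get_index(db, k: int = _KMER_K) -> PeptideIndex:
    """Build (and memoize on the database object) the search index."""
    cached = getattr(db, "_pep_index", None)
    if cached is not None and cached.k == k:
        return cached
    idx = PeptideIndex(db, k=k)
    try:
        object.__setattr__(db, "_pep_index", idx)
    except (AttributeError, TypeError):
        pass
    return idx


def _resolve_scoring(scoring: ScoringScheme | None, index: PeptideIndex) -> ScoringScheme:
    if scoring is None:
        scoring = ScoringScheme()
    if scoring.database_size is None:
        scoring = ScoringScheme(
            matrix_name=scoring.matrix_name,
            gap_open=scoring.gap_open,
            gap_extend=scoring.gap_extend,
            lambda_=scoring.lambda_,
            k=scoring.k,
            database_size=index.total_aa,
        )
    return scoring


def _translate_batch(dna_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Six-frame translate a uniform-length encoded DNA matrix.

    Returns (pep (n, 6, pmax) int8, plen (6,) int64).
    """
    table = codon_table()
    n, L = dna_mat.shape
    pmax = L // 3
    pep = np.full((n, 6, max(pmax, 1)), AA_X, dtype=np.int8)
    plen = np.zeros(6, dtype=np.int64)
    rc = np.where(dna_mat < 4, 3 - dna_mat, 4).astype(np.int8)[:, ::-1]
    for fi in range(6):
        strand = dna_mat if fi < 3 else rc
        off = fi % 3
        m = (L - off) // 3
        plen[fi] = m
        if m == 0:
            continue
        # codon index in int8 arithmetic (max value 124 fits)
        idx = strand[:, off : off + 3 * m : 3] * np.int8(25)
        idx += strand[:, off + 1 : off + 3 * m : 3] * np.int8(5)
        idx += strand[:, off + 2 : off + 3 * m : 3]
        pep[:, fi, :m] = table[idx]
    return pep, plen


def _seed_and_extend(
    pep: np.ndarray,
    plen: np.ndarray,
    index: PeptideIndex,
    scoring: ScoringScheme,
    cov_denoms: np.ndarray,
    min_bit: float,
    band_pad: int,
):
    """Core seeded search of a peptide block; returns raw hit columns."""
    n, n_frames, _ = pep.shape
    diag_off = index.max_tlen
    diag_span = int(pep.shape[2] + index.max_tlen + 2)
    need_two = np.ones(6, dtype=np.uint8)
    key_parts = []
    k = index.k
    for fi in range(n_frames):
        m = int(plen[fi])
        nk = m - k + 1
        if nk <= 0:
            continue
        if nk < _TWO_HIT_MIN_KMERS:
            need_two[fi] = 0
        codes, valid = _kmer_codes(pep[:, fi, :m], k)
        cnt = np.where(valid, index.kcount[codes], 0)
        rr, qq = np.nonzero(cnt)
        cnz = cnt[rr, qq].astype(np.int64)
        tot = int(cnz.sum())
        if tot == 0:
            continue
        starts = index.kstart[codes[rr, qq]]
        csum = np.concatenate(([0], np.cumsum(cnz)[:-1]))
        pidx = np.repeat(starts - csum, cnz) + np.arange(tot)
        tgt = index.p_target[pidx]
        tpos = index.p_pos[pidx]
        rd = np.repeat(rr, cnz)
        qp = np.repeat(qq, cnz)
        dshift = qp - tpos + diag_off
        key = ((rd * 6 + fi) * index.n_targets + tgt) * diag_span + dshift
        key_parts.append(key)
    if not key_parts:
        empty = np.empty(0)
        return (np.empty(0, np.int32),) * 3 + (empty,) * 4 + (np.empty(0, np.int32),) * 4
    keys = np.sort(np.concatenate(key_parts))
    c_read, c_frame, c_target, c_dlo, c_dhi = scan_candidates(
        keys, diag_span, index.n_targets, need_two
    )
    submat = load_matrix(scoring.matrix_name)
    score, qstart, qend, tstart, tend, cols, ident = banded_sw_batch(
        pep,
        plen,
        index.t_flat,
        index.t_off,
        c_read,
        c_frame,
        c_target,
        c_dlo,
        c_dhi,
        diag_off,
        band_pad,
        submat,
        scoring.gap_open,
        scoring.gap_extend,
    )
    bit = (scoring.lambda_ * score - math.log(scoring.k)) / math.log(2)
    keep = (score > 0) & (bit >= min_bit) & (cols > 0)
    c_read = c_read[keep]
    bit = bit[keep]
    m_aa = plen[c_frame[keep]].astype(np.float64)
    evalue = m_aa * float(scoring.database_size) * np.exp2(-bit)
    cov = (qend[keep] - qstart[keep] + 1) / cov_denoms[c_read]
    pid = 100.0 * ident[keep] / cols[keep]
    return (
        c_read,
        c_frame[keep],
        c_target[keep],
        bit,
        evalue,
        cov,
        pid,
        qstart[keep],
        qend[keep],
        tstart[keep],
        tend[keep],
    )


def search_reads(
    reads: Sequence,
    db,
    scoring: ScoringScheme | None = None,
    min_bit: float = 15.0,
    band_pad: int = 5,
    chunk_bases: int = 4_000_000,
) -> HitTable:
    """Translated search of a batch of reads against the marker database.

    ``reads`` may be plain strings or objects with ``.id``/``.seq``
    attributes.  Reads are processed in uniform-length chunks; results are
    merged into one :class:`HitTable`.
    """
    seqs: list[str] = []
    ids: list[str] = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            ids.append(f"read_{i}")
            seqs.append(r)
        else:
            ids.append(r.id)
            seqs.append(r.seq)
    index = db if isinstance(db, PeptideIndex) else get_index(db)
    scoring = _resolve_scoring(scoring, index)
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    cols: dict[str, list[np.ndarray]] = {key: [] for key in (
        "read", "frame", "target", "bit", "evalue", "cov", "pid",
        "qstart", "qend", "tstart", "tend")}
    for L in np.unique(lengths):
        if L < 3:
            continue
        (grp,) = np.nonzero(lengths == L)
        per_chunk = max(1, int(chunk_bases // max(L, 1)))
        for lo in range(0, len(grp), per_chunk):
            sub = grp[lo : lo + per_chunk]
            joined = "".join(seqs[i] for i in sub)
            mat = encode_dna(joined).reshape(len(sub), L)
            pep, plen = _translate_batch(mat)
            denom = np.full(len(sub), max(L // 3, 1), dtype=np.float64)
            out = _seed_and_extend(pep, plen, index, scoring, denom, min_bit, band_pad)
            (r, f, t, b, e, cv, p, qs, qe, ts, te) = out
            cols["read"].append(sub[r])
            cols["frame"].append(f)
            cols["target"].append(t)
            cols["bit"].append(b)
            cols["evalue"].append(e)
            cols["cov"].append(cv)
            cols["pid"].append(p)
            cols["qstart"].append(qs)
            cols["qend"].append(qe)
            cols["tstart"].append(ts)
            cols["tend"].append(te)

    def _cat(name, dtype):
        arrs = cols[name]
        return np.concatenate(arrs).astype(dtype) if arrs else np.empty(0, dtype)

    return HitTable(
        index=index,
        scoring=scoring,
        read_ids=ids,
        read_length=lengths,
        read_idx=_cat("read", np.int64),
        target_idx=_cat("target", np.int32),
        frame_idx=_cat("frame", np.int8),
        bit=_cat("bit", np.float64),
        evalue=_cat("evalue", np.float64),
        coverage=_cat("cov", np.float64),
        pid=_cat("pid", np.float64),
        qstart=_cat("qstart", np.int32),
        qend=_cat("qend", np.int32),
        tstart=_cat("tstart", np.int32),
        tend=_cat("tend", np.int32),
    )


def search_proteins(
    queries: Sequence[tuple[str, str]],
    db,
    scoring: ScoringScheme | None = None,
    min_bit: float = 10.0,
) -> HitTable:
    """Protein-protein search (no translation), same seeding and scoring.

    Coverage in the returned table is relative to the query protein length;
    target-side coverage can be computed from the target spans.
    """
    index = db if isinstance(db, PeptideIndex) else get_index(db)
    scoring = _resolve_scoring(scoring, index)
    ids = [q[0] for q in queries]
    enc = [_codec.encode_aa(q[1]) for q in queries]
    lengths = np.array([len(e) for e in enc], dtype=np.int64)
    cols: dict[str, list[np.ndarray]] = {key: [] for key in (
        "read", "frame", "target", "bit", "evalue", "cov", "pid",
        "qstart", "qend", "tstart", "tend")}
    for L in np.unique(lengths):
        if L < index.k:
            continue
        (grp,) = np.nonzero(lengths == L)
        pep = np.vstack([enc[i] for i in grp]).astype(np.int8)[:, np.newaxis, :]
        plen = np.array([L], dtype=np.int64)
        denom = np.full(len(grp), float(L))
        out = _seed_and_extend(
            pep, plen, index, scoring, denom, min_bit, band_pad=index.max_tlen
        )
        (r, f, t, b, e, cv, p, qs, qe, ts, te) = out
        cols["read"].append(grp[r])
        cols["frame"].append(f)
        cols["target"].append(t)
        cols["bit"].append(b)
        cols["evalue"].append(e)
        cols["cov"].append(cv)
        cols["pid"].append(p)
        cols["qstart"].append(qs)
        cols["qend"].append(qe)
        cols["tstart"].append(ts)
        cols["tend"].append(te)

    def _cat(name, dtype):
        arrs = cols[name]
        return np.concatenate(arrs).astype(dtype) if arrs else np.empty(0, dtype)

    return HitTable(
        index=index,
        scoring=scoring,
        read_ids=ids,
        read_length=lengths,
        read_idx=_cat("read", np.int64),
        target_idx=_cat("target", np.int32),
        frame_idx=_cat("frame", np.int8),
        bit=_cat("bit", np.float64),
        evalue=_cat("evalue", np.float64),
        coverage=_cat("cov", np.float64),
        pid=_cat("pid", np.float64),
        qstart=_cat("qstart", np.int32),
        qend=_cat("qend", np.int32),
        tstart=_cat("tstart", np.int32),
        tend=_cat("tend", np.int32),
        protein_mode=True,
    )


def translated_search(read, db, scoring: ScoringScheme | None = None) -> list[AlignmentHit]:
    """Search a single read; returns hits sorted best-first."""
    seq = read if isinstance(read, str) else read.seq
    if len(seq) < 9:
        raise ValueError("read shorter than 9 nt cannot be translated usefully")
    table = search_reads([read], db, scoring=scoring)
    return table.to_hit_lists()[0]


def top_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """Best hit by bit score; ties by lower E-value then target id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.bit_score, h.e_value, h.target_sequence_id))


def read_external_hits(path, db, read_ids: Sequence[str]) -> HitTable:
    """Import hits from an external translated search.

    Expected tab-separated columns (no header): read_id, target_sequence_id,
    bit_score, percent_identity, aligned_length, e_value, frame.  Coverage is
    derived as aligned_length / floor(read_length / 3) and read lengths are
    unknown here, so aligned_length is stored and coverage must be
    interpreted by the caller; reads absent from ``read_ids`` are an error.
    """
    index = db if isinstance(db, PeptideIndex) else get_index(db)
    scoring = _resolve_scoring(None, index)
    rid_lookup = {r: i for i, r in enumerate(read_ids)}
    tid_lookup = {s: i for i, s in enumerate(index.seq_ids)}
    rows = {key: [] for key in ("read", "target", "frame", "bit", "pid", "alen", "ev")}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise ValueError(f"line {ln}: expected 7 columns, got {len(parts)}")
            rid, tid = parts[0], parts[1]
            if rid not in rid_lookup:
                raise ValueError(f"line {ln}: unknown read id {rid!r}")
            if tid not in tid_lookup:
                raise ValueError(f"line {ln}: unknown target id {tid!r}")
            rows["read"].append(rid_lookup[rid])
            rows["target"].append(tid_lookup[tid])
            rows["bit"].append(float(parts[2]))
            rows["pid"].append(float(parts[3]))
            rows["alen"].append(int(parts[4]))
            rows["ev"].append(float(parts[5]))
            rows["frame"].append(FRAME_LABELS.index(int(parts[6])))
    alen = np.array(rows["alen"], dtype=np.int32)
    n = len(read_ids)
    return HitTable(
        index=index,
        scoring=scoring,
        read_ids=list(read_ids),
        read_length=np.zeros(n, dtype=np.int64),
        read_idx=np.array(rows["read"], dtype=np.int64),
        target_idx=np.array(rows["target"], dtype=np.int32),
        frame_idx=np.array(rows["frame"], dtype=np.int8),
        bit=np.array(rows["bit"], dtype=np.float64),
        evalue=np.array(rows["ev"], dtype=np.float64),
        coverage=alen.astype(np.float64),
        pid=np.array(rows["pid"], dtype=np.float64),
        qstart=np.zeros(len(alen), dtype=np.int32),
        qend=alen - 1,
        tstart=np.zeros(len(alen), dtype=np.int32),
        tend=alen - 1,
    )
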