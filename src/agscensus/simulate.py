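"""Synthetic marker families, genomes, communities, and shotgun read
libraries with known ground truth.

This is both the training engine and the benchmark fixture generator: it
emulates prokaryote-like genomes that carry exactly one copy of each marker
family embedded in random background DNA, assembles communities with
controlled Shannon entropy, and samples reads with a uniform error model
(substitutions : indels = 4 : 1).

Coverage bookkeeping follows the usual shotgun arithmetic: the coverage of
genome i in library j is G_ij = R_i * G_j, and the number of reads drawn is
N_ij = G_ij * S_i / L_j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._codec import codons_by_aa, encode_aa, encode_dna
from .io import Read
from .marker_db import MarkerDatabase, MarkerFamily

# Shannon entropies (bits) of the 20-member complexity tiers
TIER_ENTROPY = {"low": 1.08, "medium": 2.75, "high": None}
_TIER_MEMBERS = 20

_DNA_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _rng(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in salt])


@dataclass
class CommunityMember:
    genome_id: str
    genome_size: int  # S_i, bp
    relative_abundance: float = 0.0  # R_i
    sequence: str | None = None
    carries_markers: bool = True
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if not 0 <= self.relative_abundance <= 1:
            raise ValueError("relative_abundance out of [0, 1]")
        if self.sequence is not None and len(self.sequence) != self.genome_size:
            raise ValueError("sequence length disagrees with genome_size")


@dataclass
class CommunityProfile:
    members: list[CommunityMember]
    complexity_tag: str = "custom"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community needs at least one member")
        total = sum(m.relative_abundance for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative abundances sum to {total}, expected 1")

    def abundances(self) -> np.ndarray:
        return np.array([m.relative_abundance for m in self.members])


@dataclass(frozen=True)
class SimulationConfig:
    read_length: int  # L_j
    total_coverage: float  # G_j
    error_rate: float = 0.0
    substitution_to_indel_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 25:
            raise ValueError("read_length must be >= 25 bp")
        if self.total_coverage <= 0:
            raise ValueError("total_coverage must be positive")
        if not 0 <= self.error_rate <= 0.10:
            raise ValueError("error_rate must be within [0, 0.10]")


@dataclass(frozen=True)
class SyntheticMarkerSpec:
    n_families: int = 30
    ancestral_protein_length: int = 200
    per_genome_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if not 0 <= self.per_genome_divergence <= 0.6:
            raise ValueError("divergence must be within [0, 0.6]")


def true_ags(community: CommunityProfile) -> float:
    """Abundance-weighted mean genome size over the cellular (marker-carrying)
    members; viral-like members are excluded and the remaining abundances are
    renormalized."""
    cellular = [m for m in community.members if m.carries_markers]
    if not cellular:
        raise ValueError("community has no marker-carrying members")
    total_r = sum(m.relative_abundance for m in cellular)
    if total_r <= 0:
        raise ValueError("marker-carrying members have zero total abundance")
    return sum(m.relative_abundance * m.genome_size for m in cellular) / total_r


def shannon_entropy(abundances) -> float:
    """Shannon entropy in bits; zero-abundance members contribute nothing."""
    p = np.asarray(abundances, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative abundance")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {p.sum()}, expected 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


_AA20 = "ARNDCQEGHILKMFPSTWYV"


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA20[i] for i in rng.integers(0, 20, length))


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute ``round(divergence * len)`` residues at random positions
    with uniformly chosen different amino acids."""
    n_mut = int(round(divergence * len(protein)))
    if n_mut == 0:
        return protein
    pos = rng.choice(len(protein), size=n_mut, replace=False)
    chars = list(protein)
    for p in pos:
        alternatives = [a for a in _AA20 if a != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 19))]
    return "".join(chars)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform random synonymous codon for each residue."""
    table = codons_by_aa()
    codes = encode_aa(protein)
    out = []
    for c in codes:
        options = table[int(c)]
        out.append(options[int(rng.integers(0, len(options)))])
    return "".join(out)


def generate_marker_families(spec: SyntheticMarkerSpec) -> MarkerDatabase:
    """Ancestral synthetic marker families: one uniform-random protein per
    family; deterministic under the spec seed."""
    rng = _rng(spec.seed, 11)
    fams = []
    for i in range(spec.n_families):
        fam_id = f"fam{i:02d}"
        prot = _random_protein(rng, spec.ancestral_protein_length)
        fams.append(MarkerFamily(fam_id, [(f"{fam_id}.anc", prot)]))
    return MarkerDatabase(fams, version_tag=f"synthetic-{spec.seed}-{spec.n_families}")


def _revcomp_str(dna: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return dna.translate(comp)[::-1]


def generate_genome(
    markers: MarkerDatabase,
    size: int,
    divergence: float,
    seed: int,
    carries_markers: bool = True,
    genome_id: str = "genome",
    proteins: dict[str, str] | None = None,
    taxonomy: dict[str, str] | None = None,
) -> CommunityMember:
    """A synthetic genome of exactly ``size`` bp.

    Marker-carrying genomes embed exactly one copy of each family: the
    family's first (ancestral) protein mutated at the given divergence —
    or the explicitly supplied per-family protein — reverse-translated with
    uniform codons and placed at a non-overlapping uniform position on a
    uniform strand.  Background is i.i.d. uniform DNA.  Viral-like genomes
    (carries_markers=False) are pure random DNA.
    """
    rng = _rng(seed, 23)
    background = _DNA_BYTES[rng.integers(0, 4, size)].tobytes().decode()
    if not carries_markers:
        return CommunityMember(genome_id, size, sequence=background,
                               carries_markers=False, taxonomy=taxonomy)
    cds_list = []
    for fam in markers.families:
        if proteins is not None and fam.family_id in proteins:
            prot = proteins[fam.family_id]
        else:
            prot = mutate_protein(fam.proteins[0][1], divergence, rng)
        cds_list.append(reverse_translate(prot, rng))
    total_marker = sum(len(c) for c in cds_list)
    if size < 2 * total_marker:
        raise ValueError(
            f"genome size {size} too small to host {total_marker} bp of markers"
        )
    # exact uniform non-overlapping placement: drop the loci (in random
    # order) into the free space between them (stars-and-bars)
    order = rng.permutation(len(cds_list))
    free = size - total_marker
    cuts = np.sort(rng.integers(0, free + 1, size=len(cds_list)))
    starts = []
    consumed = 0
    for cut, k in zip(cuts, order):
        starts.append((int(cut) + consumed, int(k)))
        consumed += len(cds_list[int(k)])
    seq = list(background)
    for s, k in starts:
        cds = cds_list[k]
        if rng.integers(0, 2) == 1:
            cds = _revcomp_str(cds)
        seq[s : s + len(cds)] = cds
    return CommunityMember(genome_id, size, sequence="".join(seq), taxonomy=taxonomy)


def geometric_abundances(n: int, target_entropy: float, tol: float = 1e-4) -> np.ndarray:
    """Geometric abundance series p_k proportional to r**k, with the decay r
    found by bisection so that the Shannon entropy matches the target."""
    if target_entropy <= 0 or target_entropy >= math.log2(n):
        raise ValueError("target entropy out of attainable range")

    def entropy_of(r: float) -> float:
        p = r ** np.arange(n)
        p /= p.sum()
        return shannon_entropy(p)

    lo, hi = 1e-9, 1.0 - 1e-12
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if entropy_of(mid) < target_entropy:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15:
            break
    r = 0.5 * (lo + hi)
    if abs(entropy_of(r) - target_entropy) > tol:
        raise RuntimeError("entropy bisection failed to converge")
    p = r ** np.arange(n)
    return p / p.sum()


def build_community(
    genomes: list[CommunityMember],
    complexity: str | None = None,
    abundances=None,
    seed: int = 0,
) -> CommunityProfile:
    """Assign relative abundances by complexity tier or explicitly.

    ``high`` is uniform; ``low`` and ``medium`` are geometric series tuned to
    Shannon entropies of 1.08 and 2.75 bits (20-member tiers).  The mapping
    of abundance ranks to genomes is permuted deterministically under the
    seed, so different seeds give communities with different true AGS.
    """
    n = len(genomes)
    if n == 0:
        raise ValueError("no genomes supplied")
    if abundances is not None:
        p = np.asarray(abundances, dtype=float)
        if len(p) != n:
            raise ValueError("abundance vector length mismatch")
        p = p / p.sum()
        tag = "custom"
    else:
        if complexity not in TIER_ENTROPY:
            raise ValueError(f"unknown complexity tier {complexity!r}")
        if n != _TIER_MEMBERS:
            raise ValueError(
                f"complexity tiers are defined for {_TIER_MEMBERS}-member "
                f"communities (got {n})"
            )
        target = TIER_ENTROPY[complexity]
        if target is None:
            p = np.full(n, 1.0 / n)
        else:
            p = geometric_abundances(n, target)
        p = p[_rng(seed, 31).permutation(n)]
        tag = complexity
    members = [
        CommunityMember(
            g.genome_id,
            g.genome_size,
            relative_abundance=float(p[i]),
            sequence=g.sequence,
            carries_markers=g.carries_markers,
            taxonomy=g.taxonomy,
        )
        for i, g in enumerate(genomes)
    ]
    return CommunityProfile(members, complexity_tag=tag)


def _apply_errors_row(src: np.ndarray, L: int, err: np.ndarray, kind: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-read error application for reads containing at least one indel.

    Walk the source bases; an erroneous base is a substitution (kind < 0.8),
    a deletion (0.8 <= kind < 0.9), or an insertion of a random base before
    the source base (kind >= 0.9).  Output is truncated/filled to exactly L.
    """
    out = np.empty(L + 8, dtype=src.dtype)
    n_out = 0
    for i in range(len(src)):
        if n_out >= L:
            break
        if err[i]:
            k = kind[i]
            if k < 0.8:  # substitution
                out[n_out] = (src[i] + 1 + int(rng.integers(0, 3))) % 4
                n_out += 1
            elif k < 0.9:  # deletion
                continue
            else:  # insertion
                out[n_out] = int(rng.integers(0, 4))
                n_out += 1
                if n_out < L:
                    out[n_out] = src[i]
                    n_out += 1
        else:
            out[n_out] = src[i]
            n_out += 1
    while n_out < L:  # extremely unlikely: deletions exhausted the slack
        out[n_out] = int(rng.integers(0, 4))
        n_out += 1
    return out[:L]


def simulate_reads(
    community: CommunityProfile, cfg: SimulationConfig
) -> tuple[list[Read], dict]:
    """Shotgun library from a community: per genome N_ij = round(G_ij * S_i /
    L_j) reads at uniform positions on the circular genome, uniform strand,
    constant Q30 qualities; deterministic under the config seed."""
    L = cfg.read_length
    for m in community.members:
        if m.sequence is None:
            raise ValueError(f"member {m.genome_id} has no sequence")
        if L > m.genome_size:
            raise ValueError(f"read length {L} exceeds genome {m.genome_id}")
    e = cfg.error_rate
    # indel fraction of errors from the substitution:indel ratio (default 4:1)
    ratio = cfg.substitution_to_indel_ratio
    sub_frac = ratio / (1.0 + ratio)
    slack = 0 if e == 0 else 8 + int(3 * L * e * (1 - sub_frac))
    reads: list[Read] = []
    truth_members = []
    qual = chr(30 + 33) * L
    for mi, m in enumerate(community.members):
        rng = _rng(cfg.seed, 47, mi)
        g_i = m.relative_abundance * cfg.total_coverage
        n_reads = int(round(g_i * m.genome_size / L))
        truth_members.append(
            {
                "genome_id": m.genome_id,
                "size_bp": m.genome_size,
                "rel_abund": m.relative_abundance,
                "n_reads": n_reads,
                "carries_markers": m.carries_markers,
            }
        )
        if n_reads == 0:
            continue
        gcodes = encode_dna(m.sequence).astype(np.uint8)
        # minus-strand reads start at a uniform position on the reverse
        # complement, so deletion slack extends downstream on either strand
        rcodes = np.where(gcodes < 4, 3 - gcodes, 4).astype(np.uint8)[::-1]
        wrap_f = np.concatenate([gcodes, gcodes[: L + slack]])
        wrap_r = np.concatenate([rcodes, rcodes[: L + slack]])
        starts = rng.integers(0, m.genome_size, n_reads)
        strands = rng.integers(0, 2, n_reads)
        mat = wrap_f[starts[:, None] + np.arange(L + slack)[None, :]]
        minus = strands == 1
        if minus.any():
            mat[minus] = wrap_r[starts[minus][:, None] + np.arange(L + slack)[None, :]]
        if e > 0:
            err = rng.random((n_reads, L + slack)) < e
            kind = rng.random((n_reads, L + slack))
            has_indel = (err & (kind >= sub_frac)).any(axis=1)
            # substitution-only rows, fully vectorized
            sub_rows = ~has_indel
            sub_mask = err[sub_rows] & (kind[sub_rows] < sub_frac)
            block = mat[sub_rows]
            shift = rng.integers(1, 4, size=block.shape).astype(np.uint8)
            block[sub_mask] = (block[sub_mask] + shift[sub_mask]) % 4
            mat[sub_rows] = block
            out = np.empty((n_reads, L), dtype=np.uint8)
            out[sub_rows] = mat[sub_rows, :L]
            # rescale indel kinds onto [0,1) split 0.8/0.1/0.1 of the error mass
            for ridx in np.nonzero(has_indel)[0]:
                k = kind[ridx].copy()
                # map: k < sub_frac -> substitution (<0.8); else indel
                k2 = np.where(k < sub_frac, 0.8 * k / sub_frac,
                              0.8 + 0.2 * (k - sub_frac) / (1 - sub_frac))
                out[ridx] = _apply_errors_row(mat[ridx], L, err[ridx], k2, rng)
            mat = out
        else:
            mat = mat[:, :L]
        byte_mat = _DNA_BYTES[mat]
        for k in range(n_reads):
            reads.append(
                Read(f"{m.genome_id}|{k}", byte_mat[k].tobytes().decode(), qual)
            )
    truth = {
        "true_ags": true_ags(community),
        "read_length": L,
        "total_coverage": cfg.total_coverage,
        "error_rate": e,
        "seed": cfg.seed,
        "complexity_tag": community.complexity_tag,
        "members": truth_members,
    }
    return reads, truth


def mix_contaminants(library, contaminant_library, fraction: float, seed: int = 0):
    """Replace a fraction of the library with (marker-free) contaminant reads.

    The output keeps the library size N: ceil(fraction * N) contaminant reads
    plus the first N - ceil(fraction * N) original reads, shuffled
    deterministically.  fraction = 0 returns the library unchanged.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    library = list(library)
    n = len(library)
    n_cont = math.ceil(fraction * n)
    if n_cont == 0:
        return library
    if len(contaminant_library) < n_cont:
        raise ValueError(
            f"contaminant library has {len(contaminant_library)} reads, "
            f"need {n_cont}"
        )
    mixed = list(contaminant_library[:n_cont]) + library[: n - n_cont]
    order = _rng(seed, 59).permutation(len(mixed))
    return [mixed[i] for i in order]


def generate_taxon_panel(
    markers: MarkerDatabase,
    n_classes: int = 4,
    genera_per_class: int = 2,
    species_per_genus: int = 5,
    branch_divergence: float = 0.025,
    size_range: tuple[int, int] = (100_000, 500_000),
    seed: int = 0,
) -> tuple[MarkerDatabase, list[CommunityMember]]:
    """A panel of genomes in a three-level synthetic taxonomy (class > genus >
    species) plus the matching labeled marker database.

    Marker proteins evolve along the taxonomy: each branch (class from
    ancestor, genus from class, species from genus) substitutes
    ``branch_divergence`` of residues, so sibling species differ by ~2x,
    sibling genera by ~4x, and sibling classes by ~6x the branch divergence.
    Every genome carries exactly the marker variants recorded for it in the
    returned database, whose sequences are labeled at all three levels.
    """
    rng = _rng(seed, 71)
    fam_variants: dict[str, dict[str, str]] = {}  # genome_id -> family -> protein
    taxonomy: dict[str, dict[str, str]] = {}
    genome_meta: list[tuple[str, dict[str, str]]] = []
    for c in range(n_classes):
        class_label = f"class{c:02d}"
        class_prots = {
            f.family_id: mutate_protein(f.proteins[0][1], branch_divergence, rng)
            for f in markers.families
        }
        for g in range(genera_per_class):
            genus_label = f"{class_label}.genus{g:02d}"
            genus_prots = {
                fam: mutate_protein(p, branch_divergence, rng)
                for fam, p in class_prots.items()
            }
            for s in range(species_per_genus):
                species_label = f"{genus_label}.sp{s:02d}"
                gid = f"c{c:02d}g{g:02d}s{s:02d}"
                prots = {
                    fam: mutate_protein(p, branch_divergence, rng)
                    for fam, p in genus_prots.items()
                }
                fam_variants[gid] = prots
                labels = {
                    "species": species_label,
                    "genus": genus_label,
                    "class": class_label,
                }
                genome_meta.append((gid, labels))
    fams = []
    for f in markers.families:
        prots = [
            (f"{f.family_id}.{gid}", fam_variants[gid][f.family_id])
            for gid, _ in genome_meta
        ]
        fams.append(MarkerFamily(f.family_id, prots))
        for gid, labels in genome_meta:
            taxonomy[f"{f.family_id}.{gid}"] = labels
    panel_db = MarkerDatabase(
        fams, version_tag=f"{markers.version_tag}-panel{seed}", taxonomy=taxonomy
    )
    genomes = []
    for gi, (gid, labels) in enumerate(genome_meta):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        genomes.append(
            generate_genome(
                markers,
                size=size,
                divergence=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
                genome_id=gid,
                proteins=fam_variants[gid],
                taxonomy=labels,
            )
        )
    return panel_db, genomes
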