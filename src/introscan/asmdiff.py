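"""Assembly-vs-assembly SV discovery: anchoring, chaining, gap-arithmetic calls.

The stage mirrors the classic whole-genome-alignment workflow at desk scale:
maximal exact matches seeded at k-mers unique in both sequences stand in for
maximal unique matches, a maximal-weight collinear chain stands in for an
alignment cluster, and insertions/deletions fall out of the gap arithmetic
between consecutive anchors. Calls from many query genomes are merged into a
nonoverlapping catalog with a genome x SV presence matrix.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnchorParams",
    "Anchor",
    "SVRecord",
    "SVCatalog",
    "compute_n50",
    "find_anchors",
    "chain_anchors",
    "call_svs",
    "discover_svs",
    "merge_catalog",
    "SV_MIN_LEN",
    "SV_MAX_LEN",
]

SV_MIN_LEN = 1
SV_MAX_LEN = 10_000


@dataclass(frozen=True)
class AnchorParams:
    """Anchoring/chaining thresholds.

    min_match_len: minimum length of a maximal exact match kept as an anchor.
    min_cluster_len: minimum total anchor length of a retained chain.
    seed_k: k-mer size used to seed anchors (k-mers unique in both sequences).
    """

    min_match_len: int = 100
    min_cluster_len: int = 500
    seed_k: int = 21
    both_strands: bool = False
    # anchors may overlap by up to this many bp in a chain (breakpoint
    # micro-homology); the overlap is trimmed off during SV calling
    max_overlap: int = 50

    def __post_init__(self) -> None:
        if not self.min_match_len >= self.seed_k >= 11:
            raise ValueError("require min_match_len >= seed_k >= 11")


@dataclass(frozen=True)
class Anchor:
    """An exact-match block between reference and query (half-open, forward)."""

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start != self.qry_end - self.qry_start:
            raise ValueError("anchor ref/qry spans differ")


@dataclass(frozen=True)
class SVRecord:
    """One structural variant on reference coordinates.

    For insertions ``ref_end == ref_start`` and ``alt_sequence`` holds the
    inserted bases; for deletions the alt is empty; ``indel`` records a
    simultaneous gap on both sides (net length difference).
    """

    chrom: str
    ref_start: int
    ref_end: int
    type: str
    length: int
    alt_sequence: str = ""
    source_genome: str = ""

    def __post_init__(self) -> None:
        if self.type not in ("insertion", "deletion", "indel"):
            raise ValueError(f"bad SV type {self.type!r}")
        if self.ref_end < self.ref_start:
            raise ValueError("ref_end < ref_start")
        if self.type == "insertion" and self.ref_end != self.ref_start:
            raise ValueError("insertion must have ref_end == ref_start")
        if not SV_MIN_LEN <= self.length <= SV_MAX_LEN:
            raise ValueError(f"SV length {self.length} outside [{SV_MIN_LEN}, {SV_MAX_LEN}]")


@dataclass
class SVCatalog:
    """Merged nonoverlapping SV set plus a genome x SV presence matrix."""

    records: list[SVRecord]
    presence: pd.DataFrame  # index: genome names; columns: record ids (sv0..)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        rec = pd.DataFrame(
            [
                {
                    "sv_id": f"sv{i}",
                    "chrom": r.chrom,
                    "ref_start": r.ref_start,
                    "ref_end": r.ref_end,
                    "type": r.type,
                    "length": r.length,
                    "alt_seq": r.alt_sequence,
                    "source_genome": r.source_genome,
                }
                for i, r in enumerate(self.records)
            ]
        )
        return rec, self.presence

    def write(self, records_path: str | Path, presence_path: str | Path) -> None:
        rec, pres = self.to_frames()
        rec.to_csv(records_path, sep="\t", index=False)
        pres.to_csv(presence_path, sep="\t")


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------

def compute_n50(contig_lengths: Sequence[int]) -> int:
    """Largest L such that contigs of length >= L cover >= half the total."""
    if not contig_lengths:
        raise ValueError("empty contig list")
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("contig lengths must be positive")
    lengths = sorted(contig_lengths, reverse=True)
    half = sum(lengths) / 2
    acc = 0
    for l in lengths:
        acc += l
        if acc >= half:
            return l
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, int]:
    """Map each k-mer occurring exactly once to its position (-1 = repeated)."""
    index: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        index[kmer] = -1 if kmer in index else i
    return index


def _extend(ref: str, qry: str, ri: int, qi: int, k: int) -> tuple[int, int, int, int]:
    rs, qs = ri, qi
    while rs > 0 and qs > 0 and ref[rs - 1] == qry[qs - 1]:
        rs -= 1
        qs -= 1
    re, qe = ri + k, qi + k
    while re < len(ref) and qe < len(qry) and ref[re] == qry[qe]:
        re += 1
        qe += 1
    return rs, re, qs, qe


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]


def find_anchors(ref: str, qry: str, params: AnchorParams = AnchorParams()) -> list[Anchor]:
    """Maximal exact matches >= min_match_len seeded at k-mers unique in both.

    Forward strand always; reverse-complement query anchors only when
    ``params.both_strands`` is set. Ambiguous seeds (k-mer repeated in either
    sequence) are skipped, which keeps the result deterministic and unique.
    """
    if not ref or not qry:
        raise ValueError("sequences must be non-empty")
    anchors = _find_anchors_oriented(ref, qry, params, "+")
    if params.both_strands:
        rc = _revcomp(qry)
        for a in _find_anchors_oriented(ref, rc, params, "-"):
            # report reverse anchors in original query coordinates
            anchors.append(
                Anchor(
                    a.ref_start,
                    a.ref_end,
                    len(qry) - a.qry_end,
                    len(qry) - a.qry_start,
                    "-",
                )
            )
    anchors.sort(key=lambda a: (a.ref_start, a.qry_start, a.strand))
    return anchors


def _find_anchors_oriented(ref: str, qry: str, params: AnchorParams, strand: str) -> list[Anchor]:
    k = params.seed_k
    ref_idx = _kmer_index(ref, k)
    qry_idx = _kmer_index(qry, k)
    seen: set[tuple[int, int]] = set()  # (diagonal, ref_start) of emitted anchors
    out: list[Anchor] = []
    last: Anchor | None = None
    for qi in range(len(qry) - k + 1):
        kmer = qry[qi : qi + k]
        if qry_idx.get(kmer, -1) != qi:
            continue
        ri = ref_idx.get(kmer, -1)
        if ri < 0:
            continue
        # skip seeds inside the previously emitted anchor on the same diagonal
        if last is not None and ri - qi == last.ref_start - last.qry_start and qi + k <= last.qry_end:
            continue
        rs, re, qs, qe = _extend(ref, qry, ri, qi, k)
        if re - rs < params.min_match_len:
            continue
        key = (rs - qs, rs)
        if key in seen:
            continue
        seen.add(key)
        last = Anchor(rs, re, qs, qe, strand)
        out.append(last)
    return out


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def chain_anchors(
    anchors: Sequence[Anchor], params: AnchorParams = AnchorParams()
) -> list[list[Anchor]]:
    """Extract maximal-weight collinear chains (weight = total anchor length).

    Chains are found greedily: the maximum-weight increasing-in-both-coordinates
    non-overlapping subsequence is taken, its anchors removed, and the process
    repeats. Chains whose total anchor length falls below ``min_cluster_len``
    are discarded.
    """
    remaining = [a for a in anchors if a.strand == "+"]
    chains: list[list[Anchor]] = []
    while remaining:
        chain = _best_chain(remaining, params.max_overlap)
        # any chain over a subset weighs no more than the best over the full
        # set, so the first sub-threshold chain ends the extraction
        if not chain or sum(a.length for a in chain) < params.min_cluster_len:
            break
        chains.append(chain)
        picked = {id(a) for a in chain}
        remaining = [a for a in remaining if id(a) not in picked]
    chains.sort(key=lambda c: c[0].ref_start)
    return chains


def _best_chain(anchors: Sequence[Anchor], max_overlap: int = 0) -> list[Anchor]:
    """Max-weight chain via DP over anchors sorted by reference start."""
    arr = sorted(anchors, key=lambda a: (a.ref_start, a.qry_start))
    n = len(arr)
    if not n:
        return []
    best = [a.length for a in arr]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if (
                arr[j].ref_end <= arr[i].ref_start + max_overlap
                and arr[j].qry_end <= arr[i].qry_start + max_overlap
                and arr[j].ref_end < arr[i].ref_end
                and arr[j].qry_end < arr[i].qry_end
                and arr[j].ref_start < arr[i].ref_start
                and arr[j].qry_start < arr[i].qry_start
            ):
                cand = best[j] + arr[i].length
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(arr[end])
        end = prev[end]
    chain.reverse()
    return chain


# ---------------------------------------------------------------------------
# SV calling
# ---------------------------------------------------------------------------

def call_svs(
    chain: Sequence[Anchor],
    ref: str,
    qry: str,
    chrom: str = "chr",
    source_genome: str = "",
) -> list[SVRecord]:
    """Gap arithmetic between consecutive chain anchors.

    reference gap g_r and query gap g_q between consecutive anchors:
    g_r=0, g_q>0 -> insertion of g_q bases (alt recorded); g_q=0, g_r>0 ->
    deletion of g_r bases; both > 0 -> indel of |g_q - g_r| (only if >= 1).
    Records outside the 1 bp - 10 kb size range are dropped.

    Anchors overlapping by less than the downstream anchor's length (breakpoint
    micro-homology) are trimmed symmetrically, which preserves the gap
    difference; a containment overlap rejects the chain.
    """
    records: list[SVRecord] = []
    chain = list(chain)
    for i in range(1, len(chain)):
        a, b = chain[i - 1], chain[i]
        overlap = max(a.ref_end - b.ref_start, a.qry_end - b.qry_start, 0)
        if overlap:
            if overlap >= b.length:
                raise ValueError("overlapping anchors in chain (containment)")
            b = replace(b, ref_start=b.ref_start + overlap, qry_start=b.qry_start + overlap)
            chain[i] = b
        g_r = b.ref_start - a.ref_end
        g_q = b.qry_start - a.qry_end
        if g_r < 0 or g_q < 0:
            raise ValueError("negative gap after trimming; chain rejected")
        if g_r == 0 and g_q == 0:
            continue
        if g_r == 0:
            rec_type, length = "insertion", g_q
            alt = qry[a.qry_end : b.qry_start]
            start = end = a.ref_end
        elif g_q == 0:
            rec_type, length = "deletion", g_r
            alt = ""
            start, end = a.ref_end, b.ref_start
        else:
            length = abs(g_q - g_r)
            if length < SV_MIN_LEN:
                continue
            rec_type = "indel"
            alt = qry[a.qry_end : b.qry_start]
            start, end = a.ref_end, b.ref_start
        if not SV_MIN_LEN <= length <= SV_MAX_LEN:
            continue
        records.append(SVRecord(chrom, start, end, rec_type, length, alt, source_genome))
    return records


def discover_svs(
    ref: str,
    qry: str,
    params: AnchorParams = AnchorParams(),
    chrom: str = "chr",
    source_genome: str = "",
) -> list[SVRecord]:
    """find_anchors -> chain_anchors -> call_svs for one genome pair."""
    anchors = find_anchors(ref, qry, params)
    records: list[SVRecord] = []
    for chain in chain_anchors(anchors, params):
        records.extend(call_svs(chain, ref, qry, chrom, source_genome))
    records.sort(key=lambda r: (r.ref_start, r.ref_end, r.type))
    return records


# ---------------------------------------------------------------------------
# catalog merge
# ---------------------------------------------------------------------------

def _same_locus(a: SVRecord, b: SVRecord, ins_bp_tol: int, ins_len_tol: float, min_ro: float) -> bool:
    if a.type != b.type or a.chrom != b.chrom:
        return False
    if a.type == "insertion":
        if abs(a.ref_start - b.ref_start) > ins_bp_tol:
            return False
        lo, hi = sorted((a.length, b.length))
        return hi - lo <= ins_len_tol * hi
    inter = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
    if inter <= 0:
        return False
    return inter >= min_ro * (a.ref_end - a.ref_start) and inter >= min_ro * (b.ref_end - b.ref_start)


def merge_catalog(
    per_genome_svs: Mapping[str, Sequence[SVRecord]],
    ins_bp_tol: int = 10,
    ins_len_tol: float = 0.2,
    min_reciprocal_overlap: float = 0.5,
) -> SVCatalog:
    """Merge per-genome calls into a nonoverlapping catalog.

    Same-type records satisfying the locus rule (deletions/indels: reciprocal
    overlap >= ``min_reciprocal_overlap``; insertions: breakpoints within
    ``ins_bp_tol`` bp and lengths within ``ins_len_tol``) collapse by
    single-linkage into one cluster represented by its longest (ties: leftmost)
    record. The presence matrix marks contributing genomes. The result is
    independent of the order genomes are supplied in.
    """
    genomes = sorted(per_genome_svs)
    tagged: list[tuple[SVRecord, str]] = []
    for g in genomes:
        for r in per_genome_svs[g]:
            tagged.append((r, g))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].ref_start, t[0].ref_end, t[0].length, t[1]))

    # single-linkage clustering with a sorted sweep: compare against clusters
    # whose max end + slack reaches the current record
    parent = list(range(len(tagged)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    slack = max(ins_bp_tol, 1)
    for i in range(len(tagged)):
        ri = tagged[i][0]
        for j in range(i + 1, len(tagged)):
            rj = tagged[j][0]
            if rj.chrom != ri.chrom or rj.ref_start > max(ri.ref_end, ri.ref_start + slack):
                break
            if _same_locus(ri, rj, ins_bp_tol, ins_len_tol, min_reciprocal_overlap):
                union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(tagged)):
        clusters.setdefault(find(i), []).append(i)

    reps: list[tuple[SVRecord, frozenset[str]]] = []
    for members in clusters.values():
        recs = [tagged[i] for i in members]
        rep = max(recs, key=lambda t: (t[0].length, -t[0].ref_start))[0]
        carriers = frozenset(g for _, g in recs)
        reps.append((rep, carriers))
    reps.sort(key=lambda t: (t[0].chrom, t[0].ref_start, t[0].ref_end, t[0].type))

    records = [r for r, _ in reps]
    presence = pd.DataFrame(
        {
            f"sv{i}": [g in carriers for g in genomes]
            for i, (_, carriers) in enumerate(reps)
        },
        index=genomes,
    )
    return SVCatalog(records, presence)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_sv_table(path: str | Path) -> list[SVRecord]:
    """Read an SV table (chrom, start, end, type, length, alt_seq, genome)."""
    df = pd.read_csv(path, sep="\t", dtype={"alt_seq": str}, keep_default_na=False)
    return [
        SVRecord(
            str(row["chrom"]),
            int(row["ref_start"]),
            int(row["ref_end"]),
            str(row["type"]),
            int(row["length"]),
            str(row.get("alt_seq", "")),
            str(row.get("genome", row.get("source_genome", ""))),
        )
        for _, row in df.iterrows()
    ]


def write_sv_table(records: Iterable[SVRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "ref_start": r.ref_start,
                "ref_end": r.ref_end,
                "type": r.type,
                "length": r.length,
                "alt_seq": r.alt_sequence,
                "genome": r.source_genome,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
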