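"""TE family attribution, poly-A detection, consensus clustering, subfamilies.

SV sequences are attributed to transposable-element families by optimal local
alignment against a library of consensus sequences (match +1, mismatch -1,
gap -2). A hit is *complete* at >90% identity and >80% query coverage,
*partial* at >80% identity otherwise, else unassigned. Library consensi are
deduplicated by greedy incremental clustering at 95% global identity (longest
first), and a family's copies are split into subfamilies by recursively
finding pairs of cosegregating non-consensus states whose co-occurrence is
far beyond what their single-site frequencies predict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from scipy import stats

__all__ = [
    "TELibraryEntry",
    "TEHit",
    "CosegParams",
    "SubfamilyPartition",
    "AlignmentSummary",
    "local_align",
    "assign_family",
    "detect_polya",
    "greedy_cluster",
    "split_subfamilies",
    "read_te_library",
    "mask_polya",
]


@dataclass(frozen=True)
class TELibraryEntry:
    name: str
    te_class: str  # SINE | LINE | other
    family: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"empty consensus for {self.name}")


def read_te_library(path) -> list[TELibraryEntry]:
    """Read a TE library FASTA with ``name#class/family`` headers."""
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, rest = rec.id.partition("#")
        te_class, _, family = rest.partition("/")
        entries.append(
            TELibraryEntry(name, te_class or "other", family or name, str(rec.seq).upper())
        )
    return entries


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentSummary:
    score: float
    identity: float  # matches / aligned columns
    query_coverage: float  # aligned query bases / |query|
    target_start: int
    query_start: int


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _summarize(alignment, query_len: int) -> AlignmentSummary:
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    qspan = sum(int(e - s) for s, e in alignment.aligned[1])
    t0 = int(alignment.aligned[0][0][0]) if len(alignment.aligned[0]) else 0
    q0 = int(alignment.aligned[1][0][0]) if len(alignment.aligned[1]) else 0
    return AlignmentSummary(
        float(alignment.score), identity, qspan / query_len if query_len else 0.0, t0, q0
    )


def local_align(query: str, target: str) -> AlignmentSummary:
    """Optimal local alignment (match +1, mismatch -1, gap -2).

    Identity is matches over aligned columns (gap columns included); coverage
    is the fraction of query bases inside the aligned region. Among co-optimal
    alignments the one with the smallest target start, then smallest query
    start, is reported.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner("local")
    alignments = aligner.align(target.upper(), query.upper())
    best: Optional[AlignmentSummary] = None
    # co-optimal alignments can be numerous; cap the scan and rely on the
    # engine's deterministic enumeration order
    for i, aln in enumerate(alignments):
        s = _summarize(aln, len(query))
        if best is None or (s.target_start, s.query_start) < (best.target_start, best.query_start):
            best = s
        if i >= 15:
            break
    assert best is not None
    return best


def global_identity(a: str, b: str) -> float:
    """Identity of the optimal global alignment under the same scoring."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner("global")
    aln = next(iter(aligner.align(a.upper(), b.upper())))
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


# ---------------------------------------------------------------------------
# family assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TEHit:
    sv_id: str
    entry: Optional[TELibraryEntry]
    identity: float
    query_coverage: float
    te_status: str  # complete | partial | unassigned
    score: float = 0.0


COMPLETE_IDENTITY = 0.90
COMPLETE_COVERAGE = 0.80
PARTIAL_IDENTITY = 0.80


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgtN", "TGCAtgcaN"))[::-1]


def mask_polya(sequence: str, window: int = 15, min_a: int = 12) -> str:
    """Soft-trim a 3' poly-A tail before alignment (tail length per detect_polya)."""
    has_tail, tail_len = detect_polya(sequence, window, min_a)
    return sequence[: len(sequence) - tail_len] if has_tail and tail_len else sequence


def assign_family(
    sv_sequence: str,
    library: Sequence[TELibraryEntry],
    sv_id: str = "",
    both_strands: bool = False,
    trim_polya: bool = True,
) -> TEHit:
    """Best-scoring library hit with complete/partial/unassigned status.

    complete: identity > 0.90 and query coverage > 0.80; partial: identity
    > 0.80; otherwise unassigned. Score ties break by higher identity, then
    library order. Terminal poly-A tails are masked by default so tail-length
    variation does not depress coverage.
    """
    if not library:
        raise ValueError("empty TE library")
    query = mask_polya(sv_sequence) if trim_polya else sv_sequence
    if not query:
        query = sv_sequence
    best: Optional[tuple[float, float, int, TELibraryEntry, AlignmentSummary]] = None
    for order, entry in enumerate(library):
        candidates = [local_align(query, entry.consensus)]
        if both_strands:
            candidates.append(local_align(_revcomp(query), entry.consensus))
        s = max(candidates, key=lambda x: (x.score, x.identity))
        key = (s.score, s.identity, -order)
        if best is None or key > (best[0], best[1], -best[2]):
            best = (s.score, s.identity, order, entry, s)
    _, _, _, entry, s = best
    if s.identity > COMPLETE_IDENTITY and s.query_coverage > COMPLETE_COVERAGE:
        status = "complete"
    elif s.identity > PARTIAL_IDENTITY:
        status = "partial"
    else:
        status = "unassigned"
        entry = None
    return TEHit(sv_id, entry, s.identity, s.query_coverage, status, s.score)


# ---------------------------------------------------------------------------
# poly-A detection
# ---------------------------------------------------------------------------

def detect_polya(sequence: str, window: int = 15, min_a: int = 12) -> tuple[bool, int]:
    """3' poly-A test: >= ``min_a`` adenines within the terminal ``window``.

    The reported tail length is the longest terminal run scanning 3'→5' that
    keeps at least 9 A per 10 bases (one tolerated non-A per ten). Strand
    specific: poly-T tails do not count.
    """
    if not sequence:
        raise ValueError("empty sequence")
    tail_window = sequence[-window:].upper()
    is_tail = tail_window.count("A") >= min_a
    best = 0
    non_a = 0
    for i, base in enumerate(reversed(sequence.upper()), start=1):
        if base != "A":
            non_a += 1
        if non_a > i // 10:
            break
        if base == "A":
            best = i
    return is_tail, best


# ---------------------------------------------------------------------------
# greedy clustering (CD-HIT style)
# ---------------------------------------------------------------------------

def greedy_cluster(
    consensi: Sequence[tuple[str, str]] | Sequence[str],
    identity_threshold: float = 0.95,
) -> list[list[str]]:
    """Greedy incremental clustering at global identity >= threshold.

    Input: (name, sequence) pairs (bare sequences get positional names).
    Sequences are processed longest first (ties by name); each joins the first
    existing representative it matches at >= the identity threshold, else it
    founds a new cluster. Returns clusters as name lists, representative first.
    """
    if not consensi:
        raise ValueError("empty input")
    named = [
        item if isinstance(item, tuple) else (f"seq{i}", item)
        for i, item in enumerate(consensi)
    ]
    named.sort(key=lambda t: (-len(t[1]), t[0]))
    reps: list[tuple[str, str]] = []
    clusters: list[list[str]] = []
    for name, seq in named:
        placed = False
        for ci, (_, rep_seq) in enumerate(reps):
            if global_identity(seq, rep_seq) >= identity_threshold:
                clusters[ci].append(name)
                placed = True
                break
        if not placed:
            reps.append((name, seq))
            clusters.append([name])
    return clusters


# ---------------------------------------------------------------------------
# subfamily splitting by cosegregating mutations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CosegParams:
    min_subfamily_size: int = 30
    p_threshold: float = 1e-4
    max_depth: int = 8

    def __post_init__(self) -> None:
        if self.min_subfamily_size < 2:
            raise ValueError("min_subfamily_size must be >= 2")


@dataclass
class SubfamilyPartition:
    assignment: dict[str, int]  # copy_id -> subfamily index
    consensi: list[str]  # per-subfamily consensus
    splits: list[dict]  # per accepted split: p, sites ((pos, state), (pos, state))

    @property
    def n_subfamilies(self) -> int:
        return len(self.consensi)


def _consensus_of(matrix: np.ndarray) -> np.ndarray:
    """Column-wise majority base (ties: lexicographically smallest)."""
    cons = np.empty(matrix.shape[1], dtype=matrix.dtype)
    for j in range(matrix.shape[1]):
        vals, counts = np.unique(matrix[:, j], return_counts=True)
        cons[j] = vals[np.lexsort((vals, -counts))[0]]
    return cons


def _best_coseg_pair(matrix: np.ndarray, cons: np.ndarray, min_size: int):
    """Best (p, (pos_i, state_i), (pos_j, state_j), carrier mask) or None.

    Candidate sites are consensus columns with >= min_size copies of one
    non-consensus state; the pair p-value is the upper binomial tail of the
    observed co-carrier count under independence of the two site frequencies.
    """
    n = matrix.shape[0]
    site_states: list[tuple[int, bytes, np.ndarray]] = []
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        non = col != cons[j]
        if int(non.sum()) < min_size:
            continue
        vals, counts = np.unique(col[non], return_counts=True)
        for v, c in zip(vals, counts):
            if c >= min_size:
                site_states.append((j, v, col == v))
    best = None
    for a in range(len(site_states)):
        ja, va, ma = site_states[a]
        for b in range(a + 1, len(site_states)):
            jb, vb, mb = site_states[b]
            if ja == jb:
                continue
            both = ma & mb
            k = int(both.sum())
            if k < min_size or n - k < min_size:
                continue
            p_null = (ma.mean()) * (mb.mean())
            p = float(stats.binom.sf(k - 1, n, p_null))
            if best is None or p < best[0]:
                best = (p, (ja, va), (jb, vb), both)
    return best


def split_subfamilies(
    copies: dict[str, str] | Sequence[tuple[str, str]],
    params: CosegParams = CosegParams(),
) -> SubfamilyPartition:
    """Recursive subfamily partition of consensus-aligned TE copies.

    All copies must be the same length (columns indexed on the family
    consensus; substitution-only alignment). At each node the most significant
    cosegregating pair of non-consensus states is tested; if its binomial
    co-occurrence p-value beats ``p_threshold`` and both resulting groups hold
    at least ``min_subfamily_size`` copies, the family splits on that pair and
    recursion continues in each half.
    """
    items = list(copies.items()) if isinstance(copies, dict) else list(copies)
    if not items:
        raise ValueError("no copies")
    names = [n for n, _ in items]
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError("copies must be aligned to equal length")
    matrix = np.array([list(s.upper()) for _, s in items], dtype="U1").astype("S1")

    assignment: dict[str, int] = {}
    consensi: list[str] = []
    splits: list[dict] = []

    def recurse(idx: np.ndarray, depth: int) -> None:
        sub = matrix[idx]
        cons = _consensus_of(sub)
        if len(idx) >= 2 * params.min_subfamily_size and depth < params.max_depth:
            found = _best_coseg_pair(sub, cons, params.min_subfamily_size)
            if found is not None and found[0] < params.p_threshold:
                p, site_a, site_b, carrier = found
                splits.append(
                    {
                        "p": p,
                        "sites": (
                            (int(site_a[0]), site_a[1].decode()),
                            (int(site_b[0]), site_b[1].decode()),
                        ),
                        "n_carrier": int(carrier.sum()),
                        "n_total": int(len(idx)),
                    }
                )
                recurse(idx[carrier], depth + 1)
                recurse(idx[~carrier], depth + 1)
                return
        sf = len(consensi)
        consensi.append(cons.tobytes().decode())
        for i in idx:
            assignment[names[i]] = sf

    recurse(np.arange(len(items)), 0)
    return SubfamilyPartition(assignment, consensi, splits)
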