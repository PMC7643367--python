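"""Read-backed presence/absence genotyping of panel SVs.

For each SV a *local reference* is cut from a genome that carries the variant
sequence: 200 bp of left flank, the SV sequence, 200 bp of right flank. Five
regions partition it::

    R1 (195 bp) | R2 (5 bp) | R3 (SV span) | R4 (5 bp) | R5 (195 bp)

R2/R4 straddle the breakpoints. An individual's quality-controlled reads are
mapped end-to-end (ungapped, small mismatch budget) to the local reference,
and the SV is called *present* iff

* covered fraction of R3 >= 0.60,
* R2 and R4 completely covered,
* covered fraction of R1 and of R5 each >= 0.50,

all thresholds inclusive — a carrier's reads tile the whole local reference,
while a non-carrier's reads cannot span the breakpoints. Concordance then
compares the calls with the expectation each pattern implies per population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import Read

__all__ = [
    "QCParams",
    "RegionSet",
    "GenotypeCall",
    "Placement",
    "qc_reads",
    "build_local_reference",
    "map_reads",
    "genotype",
    "concordance",
    "expected_presence",
]


@dataclass(frozen=True)
class QCParams:
    """Read QC thresholds (Phred scale)."""

    min_base_q: int = 20
    max_lowq_frac: float = 0.30
    adapters: tuple[str, ...] = ()
    trim_3prime_below: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_lowq_frac <= 1.0:
            raise ValueError("max_lowq_frac must be in [0,1]")


def qc_reads(reads: Iterable[Read], params: QCParams = QCParams()) -> list[Read]:
    """Filter and trim reads.

    1. drop reads containing any adapter as an exact substring;
    2. trim the longest 3' suffix whose bases are all below
       ``trim_3prime_below``;
    3. drop reads whose fraction of low-quality bases (Q <= ``min_base_q``)
       or Ns exceeds ``max_lowq_frac``; drop empty reads.
    """
    kept: list[Read] = []
    for read in reads:
        if len(read.sequence) != len(read.quality):
            raise ValueError(f"read {read.name}: sequence/quality length mismatch")
        if any(ad and ad in read.sequence for ad in params.adapters):
            continue
        quals = np.frombuffer(read.quality.encode(), dtype=np.uint8).astype(int) - 33
        end = len(quals)
        while end > 0 and quals[end - 1] < params.trim_3prime_below:
            end -= 1
        if end == 0:
            continue
        seq, qual = read.sequence[:end], read.quality[:end]
        q = quals[:end]
        is_n = np.frombuffer(seq.encode(), dtype="S1") == b"N"
        lowq = (q <= params.min_base_q) | is_n
        if lowq.mean() > params.max_lowq_frac:
            continue
        kept.append(Read(read.name, seq, qual) if end != len(read.sequence) else read)
    return kept


@dataclass(frozen=True)
class RegionSet:
    """R1..R5 half-open intervals on the local reference."""

    R1: tuple[int, int]
    R2: tuple[int, int]
    R3: tuple[int, int]
    R4: tuple[int, int]
    R5: tuple[int, int]
    flank: int = 200

    def __post_init__(self) -> None:
        sizes = {
            "R1": self.R1[1] - self.R1[0],
            "R2": self.R2[1] - self.R2[0],
            "R4": self.R4[1] - self.R4[0],
            "R5": self.R5[1] - self.R5[0],
        }
        if sizes["R1"] != self.flank - 5 or sizes["R5"] != self.flank - 5:
            raise ValueError("R1/R5 must be flank-5 bp")
        if sizes["R2"] != 5 or sizes["R4"] != 5:
            raise ValueError("R2/R4 must be 5 bp")
        order = (self.R1, self.R2, self.R3, self.R4, self.R5)
        for a, b in zip(order, order[1:]):
            if a[1] != b[0]:
                raise ValueError("regions must be contiguous in order R1..R5")

    @property
    def regions(self) -> dict[str, tuple[int, int]]:
        return {"R1": self.R1, "R2": self.R2, "R3": self.R3, "R4": self.R4, "R5": self.R5}

    @property
    def total_length(self) -> int:
        return self.R5[1]


def build_local_reference(
    carrier_genome: str,
    sv_start: int,
    sv_length: int,
    flank: int = 200,
) -> tuple[str, RegionSet]:
    """Cut flank + SV + flank from a genome that CARRIES the SV sequence.

    ``sv_start``/``sv_length`` locate the variant sequence on the carrier
    genome's own coordinates (for a presence-type SV that is the carrier of
    the insertion; for an absence-type SV, a genome still holding the
    segment — typically the reference itself).
    """
    if sv_length < 1:
        raise ValueError("sv_length must be >= 1")
    if sv_start - flank < 0 or sv_start + sv_length + flank > len(carrier_genome):
        raise ValueError("flank does not fit inside the genome at this SV")
    seq = carrier_genome[sv_start - flank : sv_start + sv_length + flank]
    r3 = (flank, flank + sv_length)
    regions = RegionSet(
        R1=(0, flank - 5),
        R2=(flank - 5, flank),
        R3=r3,
        R4=(r3[1], r3[1] + 5),
        R5=(r3[1] + 5, r3[1] + flank),
        flank=flank,
    )
    return seq, regions


def local_reference_for_sv(
    reference: str,
    ref_start: int,
    ref_end: int,
    alt_sequence: str = "",
    flank: int = 200,
) -> tuple[str, RegionSet]:
    """Local reference for a catalog SV, choosing a genome that carries it.

    Insertions (``ref_end == ref_start``, non-empty ``alt_sequence``) splice
    the insert into the reference flanks — equivalent to cutting from a
    carrier genome. Deletions use the reference itself, which still holds the
    deleted segment.
    """
    if ref_end == ref_start:
        if not alt_sequence:
            raise ValueError("insertion SV needs its alt_sequence")
        if ref_start - flank < 0 or ref_start + flank > len(reference):
            raise ValueError("flank does not fit inside the reference at this SV")
        seq = reference[ref_start - flank : ref_start] + alt_sequence + reference[ref_start : ref_start + flank]
        carrier = seq
        return build_local_reference(carrier, flank, len(alt_sequence), flank)
    return build_local_reference(reference, ref_start, ref_end - ref_start, flank)


@dataclass(frozen=True)
class Placement:
    read_name: str
    start: int  # 0-based on the local reference
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype="S1")


def map_reads(
    reads: Sequence[Read],
    local_ref: str,
    max_mismatches: int = 2,
) -> list[Placement]:
    """All end-to-end ungapped placements with <= ``max_mismatches``.

    Candidate positions come from exact seed hits (pigeonhole: a read split
    into ``max_mismatches + 1`` chunks must place at least one chunk exactly),
    then each candidate is verified by a full Hamming comparison, so the
    output equals a brute-force scan. Reads longer than the local reference
    are skipped. Output is sorted by (position, read name).
    """
    ref = _encode(local_ref)
    L = len(ref)
    # seed index: chunk length floor(read_len / (mm+1)) varies per read length,
    # so index k-mers lazily per distinct chunk length
    kmer_index: dict[int, dict[bytes, list[int]]] = {}

    def index_for(k: int) -> dict[bytes, list[int]]:
        if k not in kmer_index:
            idx: dict[bytes, list[int]] = {}
            raw = local_ref.upper().encode()
            for i in range(L - k + 1):
                idx.setdefault(raw[i : i + k], []).append(i)
            kmer_index[k] = idx
        return kmer_index[k]

    placements: list[Placement] = []
    for read in reads:
        rlen = len(read.sequence)
        if rlen > L or rlen == 0:
            continue
        rarr = _encode(read.sequence)
        n_chunks = max_mismatches + 1
        k = rlen // n_chunks
        candidates: set[int] = set()
        if k >= 8:
            idx = index_for(k)
            raw = read.sequence.upper().encode()
            for c in range(n_chunks):
                off = c * k
                for hit in idx.get(raw[off : off + k], ()):
                    pos = hit - off
                    if 0 <= pos <= L - rlen:
                        candidates.add(pos)
        else:  # short reads: brute force
            candidates = set(range(L - rlen + 1))
        for pos in candidates:
            mm = int((ref[pos : pos + rlen] != rarr).sum())
            if mm <= max_mismatches:
                placements.append(Placement(read.name, pos, mm, rlen))
    placements.sort(key=lambda p: (p.start, p.read_name))
    return placements


@dataclass(frozen=True)
class GenotypeCall:
    individual: str
    sv_id: str
    call: str  # "present" | "absent"
    covered_fractions: tuple[float, float, float, float, float]  # R1..R5
    low_coverage: bool = False  # warning only, not part of the decision


def genotype(
    placements: Sequence[Placement],
    regions: RegionSet,
    individual: str = "",
    sv_id: str = "",
) -> GenotypeCall:
    """Apply the four coverage criteria to the union of read placements."""
    covered = np.zeros(regions.total_length, dtype=bool)
    for p in placements:
        covered[max(p.start, 0) : min(p.end, regions.total_length)] = True
    fracs = []
    for name in ("R1", "R2", "R3", "R4", "R5"):
        lo, hi = regions.regions[name]
        fracs.append(float(covered[lo:hi].mean()) if hi > lo else 1.0)
    f1, f2, f3, f4, f5 = fracs
    present = f3 >= 0.60 and f2 == 1.0 and f4 == 1.0 and f1 >= 0.50 and f5 >= 0.50
    return GenotypeCall(
        individual,
        sv_id,
        "present" if present else "absent",
        tuple(fracs),
        low_coverage=len(placements) < 5,
    )


def expected_presence(pattern: str, group: str) -> bool:
    """The call a pattern's definition implies for an individual's group.

    The local reference always represents the sequence the pattern names:
    presence-type patterns (A-p, SA-p) expect ``present`` in their named
    group; absence-type patterns (A-a, SA-a) expect ``present`` in the
    complementary group, which is the one carrying the sequence.
    """
    asian = group in ("ASIA_N", "ASIA_S", "TIBET", "CROSS")
    south = group in ("ASIA_S", "CROSS")
    if pattern == "A-p":
        return asian
    if pattern == "A-a":
        return not asian
    if pattern == "SA-p":
        return south
    if pattern == "SA-a":
        return not south
    raise ValueError(f"unknown pattern {pattern!r}")


def concordance(
    calls: Sequence[GenotypeCall],
    sv_patterns: Mapping[str, str],
    individual_groups: Mapping[str, str],
) -> dict:
    """Fraction of genotype calls matching the pattern-implied expectation.

    Returns overall, per-pattern and per-group rates, each as
    ``{"rate": float, "n": int}``.
    """
    if not calls:
        raise ValueError("no genotype calls")
    rows = []
    for c in calls:
        if c.individual not in individual_groups:
            raise ValueError(f"individual {c.individual!r} has no group assignment")
        pattern = sv_patterns[c.sv_id]
        exp = expected_presence(pattern, individual_groups[c.individual])
        rows.append(
            {
                "individual": c.individual,
                "group": individual_groups[c.individual],
                "sv_id": c.sv_id,
                "pattern": pattern,
                "match": (c.call == "present") == exp,
            }
        )
    df = pd.DataFrame(rows)

    def rate(sub: pd.DataFrame) -> dict:
        return {"rate": float(sub["match"].mean()), "n": int(len(sub))}

    per_pattern = {}
    for pat, sub in df.groupby("pattern"):
        per_pattern[pat] = rate(sub)
    # the two broad patterns aggregate their presence/absence flavours
    for broad in ("A", "SA"):
        sub = df[df["pattern"].str.startswith(broad + "-")]
        if len(sub):
            per_pattern[broad] = rate(sub)
    per_group = {grp: rate(sub) for grp, sub in df.groupby("group")}
    return {"overall": rate(df), "per_pattern": per_pattern, "per_group": per_group}
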