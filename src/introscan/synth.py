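"""Synthetic data generation for the SV-pattern pipeline.

Everything downstream of this module consumes plain FASTA/FASTQ/TSV, so the
generator stands in for the real inputs of an assembly-comparison study: a
reference chromosome window, derived genomes per population carrying
population-patterned insertions/deletions, transposable-element (TE) copies
diverged from a library consensus under a substitution model with an elevated
CpG rate, and error-bearing single-end short reads.

All randomness flows through :class:`numpy.random.Generator` seeded explicitly;
every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Population",
    "SimConfig",
    "TruthSV",
    "generate_reference",
    "plant_svs",
    "evolve_te_copies",
    "simulate_reads",
    "Read",
    "write_fasta",
    "write_fastq",
    "simulate_dataset",
    "DEFAULT_TE_LIBRARY",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
# transition partner, then the two transversion partners, per base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

VALID_GROUPS = frozenset({"EUR", "ASIA_N", "ASIA_S", "TIBET", "OUTGROUP", "CROSS"})


@dataclass(frozen=True)
class Population:
    """A simulated population: a name, a broad group label, and a genome count."""

    name: str
    group: str
    n_genomes: int = 1

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {sorted(VALID_GROUPS)}")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic dataset.

    ``pattern_window_SA`` / ``pattern_window_A`` are half-open bp intervals on
    the reference emulating the two adjacent low-recombination X-chromosome
    windows in which the South-Asia and Europe/Asia patterns live.
    """

    seed: int = 0
    genome_length: int = 200_000
    gc_fraction: float = 0.42
    populations: list[Population] = field(
        default_factory=lambda: [
            Population("EUR_dom", "EUR", 2),
            Population("EUR_wild", "EUR", 2),
            Population("ASIA_N_dom", "ASIA_N", 2),
            Population("ASIA_N_wild", "ASIA_N", 2),
            Population("ASIA_S_wild", "ASIA_S", 2),
            Population("TIBET_wild", "TIBET", 1),
        ]
    )
    pattern_window_SA: tuple[int, int] = (20_000, 90_000)
    pattern_window_A: tuple[int, int] = (100_000, 190_000)
    read_length: int = 100
    depth: float = 20.0
    error_rate: float = 0.001
    te_divergence: float = 0.05
    cpg_multiplier: float = 10.0
    polya_tail: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0,1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0,1]")
        a, b = self.pattern_window_SA
        c, d = self.pattern_window_A
        for lo, hi in ((a, b), (c, d)):
            if not (0 <= lo < hi <= self.genome_length):
                raise ValueError("pattern windows must be half-open intervals within the genome")
        if max(a, c) < min(b, d):
            raise ValueError("pattern windows must be disjoint")
        self.populations = [
            p if isinstance(p, Population) else Population(**p) for p in self.populations
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("pattern_window_SA", "pattern_window_A"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["pattern_window_SA"] = list(self.pattern_window_SA)
        raw["pattern_window_A"] = list(self.pattern_window_A)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class TruthSV:
    """Ground truth for one planted variant, on reference coordinates (0-based).

    ``type`` is ``insertion`` (sequence added between ``ref_position`` and the
    next reference base of carrier genomes) or ``deletion`` (carriers lack
    ``sequence``, which equals the reference segment starting at
    ``ref_position``).
    """

    ref_position: int
    type: str
    sequence: str
    carrier_populations: frozenset[str]
    te_source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.type not in ("insertion", "deletion"):
            raise ValueError(f"bad SV type {self.type!r}")
        if len(self.sequence) < 1:
            raise ValueError("SV sequence must be non-empty")
        if not self.carrier_populations:
            raise ValueError("carrier set must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def ref_end(self) -> int:
        """Half-open end of the affected reference span (== start for insertions)."""
        return self.ref_position + (self.length if self.type == "deletion" else 0)


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def generate_reference(length: int, gc: float, seed: int) -> str:
    """Draw an i.i.d. random DNA sequence with P(G)+P(C) = ``gc``."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0,1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return BASES[idx].tobytes().decode()


def plant_svs(
    reference: str,
    panel: Sequence[TruthSV],
    config: SimConfig,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Apply a panel of variants to per-population derived genomes.

    Returns ``(genomes, truth)`` where ``genomes`` maps population name to its
    list of derived genome sequences (all genomes of a population share the
    population's carrier status — the study region is treated as haploid and
    fixed within populations) and ``truth`` is a tidy table with one row per
    (genome, SV) recording presence of the variant sequence in that genome.

    Panel entries must be sorted by position and non-overlapping on the
    reference; cumulative insertion/deletion offsets are applied left-to-right.
    """
    panel = list(panel)
    for prev, nxt in zip(panel, panel[1:]):
        if nxt.ref_position <= prev.ref_position:
            raise ValueError("panel positions must be strictly increasing")
        if nxt.ref_position < prev.ref_end:
            raise ValueError(
                f"overlapping panel entries at {prev.ref_position} and {nxt.ref_position}"
            )
    if panel and panel[-1].ref_end > len(reference):
        raise ValueError("panel extends past the reference")

    genomes: dict[str, list[str]] = {}
    rows = []
    for pop in config.populations:
        carried = [sv for sv in panel if pop.name in sv.carrier_populations]
        derived = _apply_svs(reference, carried)
        genomes[pop.name] = [derived] * pop.n_genomes
        for i in range(pop.n_genomes):
            gname = f"{pop.name}_g{i}"
            for j, sv in enumerate(panel):
                rows.append(
                    {
                        "genome": gname,
                        "population": pop.name,
                        "group": pop.group,
                        "sv_index": j,
                        "ref_start": sv.ref_position,
                        "ref_end": sv.ref_end,
                        "type": sv.type,
                        "length": sv.length,
                        "te_source": sv.te_source or "",
                        "carries_sv": pop.name in sv.carrier_populations,
                    }
                )
    truth = pd.DataFrame(
        rows,
        columns=[
            "genome",
            "population",
            "group",
            "sv_index",
            "ref_start",
            "ref_end",
            "type",
            "length",
            "te_source",
            "carries_sv",
        ],
    )
    return genomes, truth


def _apply_svs(reference: str, svs: Sequence[TruthSV]) -> str:
    parts = []
    cursor = 0
    for sv in svs:
        parts.append(reference[cursor : sv.ref_position])
        if sv.type == "insertion":
            parts.append(sv.sequence)
            cursor = sv.ref_position
        else:
            cursor = sv.ref_position + sv.length
    parts.append(reference[cursor:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# TE copy evolution
# ---------------------------------------------------------------------------

def _cpg_site_mask(consensus: str) -> np.ndarray:
    """Boolean mask of sites inside a CpG dinucleotide of the consensus."""
    arr = np.frombuffer(consensus.encode(), dtype="S1")
    mask = np.zeros(len(consensus), dtype=bool)
    if len(consensus) >= 2:
        cg = (arr[:-1] == b"C") & (arr[1:] == b"G")
        mask[:-1] |= cg
        mask[1:] |= cg
    return mask


def evolve_te_copies(
    consensus: str,
    n: int,
    target_divergence: float,
    cpg_multiplier: float = 1.0,
    seed: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Simulate ``n`` TE copies diverged from ``consensus``.

    Each site substitutes independently with probability ``target_divergence``
    (sites inside a consensus CpG dinucleotide: ``cpg_multiplier`` times that,
    capped at 0.95). Substitutions are transitions vs transversions at 2:1.
    Returns the copies and the true realized per-copy divergence
    (substituted sites / length).
    """
    if not 0.0 <= target_divergence < 0.75:
        raise ValueError("target_divergence must be in [0, 0.75)")
    if cpg_multiplier < 1.0:
        raise ValueError("cpg_multiplier must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(consensus)
    site_p = np.full(L, target_divergence)
    site_p[_cpg_site_mask(consensus)] = min(target_divergence * cpg_multiplier, 0.95)

    copies = []
    true_div = np.empty(n)
    cons = list(consensus)
    for i in range(n):
        hit = rng.random(L) < site_p
        copy = cons.copy()
        n_sub = int(hit.sum())
        if n_sub:
            kinds = rng.random(n_sub)  # <2/3 transition, else transversion
            picks = rng.integers(0, 2, size=n_sub)
            for j, pos in enumerate(np.flatnonzero(hit)):
                base = cons[pos]
                if base not in _TRANSITION:  # leave ambiguity codes untouched
                    hit[pos] = False
                    continue
                if kinds[j] < 2 / 3:
                    copy[pos] = _TRANSITION[base]
                else:
                    copy[pos] = _TRANSVERSIONS[base][picks[j]]
            n_sub = int(hit.sum())
        copies.append("".join(copy))
        true_div[i] = n_sub / L if L else 0.0
    return copies, true_div


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Read:
    """A single-end read with its Phred+33 quality string."""

    name: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.name}: sequence/quality length mismatch")


def simulate_reads(
    genome: str,
    read_length: int,
    depth: float,
    error_rate: float,
    seed: int = 0,
    name_prefix: str = "read",
) -> list[Read]:
    """Uniformly placed single-end reads at the requested fold-coverage.

    Read count = round(depth * |genome| / read_length). Substitution errors
    are i.i.d. per base at ``error_rate``; every base gets the Phred quality
    matching that error rate (capped at Q40), so qualities encode the model.
    """
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    n_reads = int(round(depth * len(genome) / read_length))
    if n_reads <= 0:
        return []
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * np.log10(error_rate))))
    qual = chr(q + 33) * read_length
    garr = np.frombuffer(genome.encode(), dtype="S1")
    reads = []
    for i, s in enumerate(starts):
        seq = garr[s : s + read_length].copy()
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            for pos in errs:
                base = seq[pos].decode()
                alts = [b for b in "ACGT" if b != base]
                seq[pos] = alts[rng.integers(0, 3)].encode()
        reads.append(Read(f"{name_prefix}_{i}_{s}", seq.tobytes().decode(), qual))
    return reads


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (Phred+33)
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str] | Sequence[tuple[str, str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    items = records.items() if isinstance(records, dict) else records
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in items),
        str(path),
        "fasta",
    )


def write_fastq(reads: Sequence[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[Read]:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, str(rec.seq), qual))
    return reads


# ---------------------------------------------------------------------------
# end-to-end dataset
# ---------------------------------------------------------------------------

# Compact stand-ins for the porcine SINE (PRE) and LINE (L1) consensus families.
# Synthetic consensi: random draws frozen by seed at import cost zero — they are
# regenerated deterministically, not stored.
def _library_consensus(name: str, length: int, seed: int, gc: float = 0.45) -> str:
    return generate_reference(length, gc, seed)


DEFAULT_TE_LIBRARY: dict[str, dict[str, str]] = {
    "PRE1-SS": {"class": "SINE", "family": "PRE1-SS", "consensus": _library_consensus("PRE1-SS", 231, 101)},
    "PRE0-SS": {"class": "SINE", "family": "PRE0-SS", "consensus": _library_consensus("PRE0-SS", 246, 102)},
    "L1-SS": {"class": "LINE", "family": "L1-SS", "consensus": _library_consensus("L1-SS", 2000, 103)},
}


def _pattern_carriers(pattern: str, config: SimConfig) -> frozenset[str]:
    eur = [p.name for p in config.populations if p.group == "EUR"]
    asia = [p.name for p in config.populations if p.group in ("ASIA_N", "ASIA_S", "TIBET", "CROSS")]
    south = [p.name for p in config.populations if p.group in ("ASIA_S", "CROSS")]
    non_south = [p.name for p in config.populations if p.group in ("EUR", "ASIA_N", "TIBET")]
    table = {
        # carriers of the *variant call* relative to the reference (EUR-like):
        # presence patterns are insertions in the named group, absence patterns
        # are deletions in the complementary group.
        "A-p": asia,
        "A-a": asia,  # deletion carried by Asians: sequence present only in EUR
        "SA-p": south,
        "SA-a": south,  # deletion carried by South Asians
    }
    return frozenset(table[pattern])


def build_panel(
    config: SimConfig,
    n_per_pattern: int = 3,
    sv_length_range: tuple[int, int] = (150, 2000),
    rng: np.random.Generator | None = None,
    library: dict[str, dict[str, str]] | None = None,
) -> list[TruthSV]:
    """Plant a pattern-structured SV panel inside the two windows.

    Insertions draw their sequence from a TE library consensus passed through
    :func:`evolve_te_copies` and receive a 3' poly-A tail; deletions remove a
    reference segment. Patterns A-p/A-a go to the A window, SA-p/SA-a to the
    SA window.
    """
    rng = rng or np.random.default_rng(config.seed + 17)
    library = library or DEFAULT_TE_LIBRARY
    fam_names = sorted(library)
    reference = None  # deletions reference sequence filled in by simulate_dataset
    placements = []
    specs = []
    for pattern in ("SA-a", "SA-p", "A-a", "A-p"):
        window = config.pattern_window_SA if pattern.startswith("SA") else config.pattern_window_A
        for _ in range(n_per_pattern):
            specs.append((pattern, window))
    # lay SVs out left-to-right with at least 300 bp of unique flank between them
    specs.sort(key=lambda s: s[1][0])
    panel: list[TruthSV] = []
    by_window: dict[tuple[int, int], list[tuple[str, tuple[int, int]]]] = {}
    for pattern, window in specs:
        by_window.setdefault(window, []).append((pattern, window))
    for window, items in sorted(by_window.items()):
        lo, hi = window
        slots = np.linspace(lo + 500, hi - 3000, num=len(items)).astype(int)
        # deletions must not run into the next slot (or window end)
        spacing = int(slots[1] - slots[0]) if len(slots) > 1 else hi - 3000 - lo - 500
        max_len = max(min(sv_length_range[1], spacing - 600), sv_length_range[0])
        rng.shuffle(items)
        for (pattern, _), pos in zip(items, slots):
            # log-uniform lengths: most SVs are short, a tail reaches the cap
            length = int(
                round(
                    np.exp(
                        rng.uniform(np.log(sv_length_range[0]), np.log(sv_length_range[1] + 1))
                    )
                )
            )
            length = min(max(length, sv_length_range[0]), max_len)
            sv_type = "insertion" if pattern.endswith("p") else "deletion"
            if sv_type == "insertion":
                fam = fam_names[int(rng.integers(0, len(fam_names)))]
                cons = library[fam]["consensus"]
                if length > len(cons) + config.polya_tail:
                    length = len(cons) + config.polya_tail
                body_len = length - config.polya_tail
                copy, _ = evolve_te_copies(
                    cons[:body_len],
                    1,
                    config.te_divergence,
                    config.cpg_multiplier,
                    seed=int(rng.integers(0, 2**31)),
                )
                seq = copy[0] + "A" * config.polya_tail
                te_source: Optional[str] = fam
            else:
                seq = "?" * length  # placeholder; resolved against the reference
                te_source = None
            panel.append(
                TruthSV(int(pos), sv_type, seq, _pattern_carriers(pattern, config), te_source)
            )
    panel.sort(key=lambda sv: sv.ref_position)
    return panel


def simulate_dataset(
    config: SimConfig,
    outdir: str | Path | None = None,
    n_per_pattern: int = 3,
    sv_length_range: tuple[int, int] = (150, 2000),
):
    """Generate reference, derived genomes, truth table and reads for a config.

    Returns a dict with keys ``reference``, ``genomes`` (population → list of
    sequences), ``truth`` (DataFrame), ``panel`` (list of TruthSV) and
    ``reads`` (genome name → list of Read). If ``outdir`` is given, FASTA,
    FASTQ and the truth TSV are written there.
    """
    reference = generate_reference(config.genome_length, config.gc_fraction, config.seed)
    panel = build_panel(config, n_per_pattern=n_per_pattern, sv_length_range=sv_length_range)
    # resolve deletion placeholder sequences against the reference
    panel = [
        dataclasses.replace(sv, sequence=reference[sv.ref_position : sv.ref_position + sv.length])
        if sv.type == "deletion"
        else sv
        for sv in panel
    ]
    genomes, truth = plant_svs(reference, panel, config)
    reads: dict[str, list[Read]] = {}
    rng = np.random.default_rng(config.seed + 4242)
    for pop in config.populations:
        for i, seq in enumerate(genomes[pop.name]):
            gname = f"{pop.name}_g{i}"
            reads[gname] = simulate_reads(
                seq,
                config.read_length,
                config.depth,
                config.error_rate,
                seed=int(rng.integers(0, 2**31)),
                name_prefix=gname,
            )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta({"ref": reference}, outdir / "reference.fa")
        for pop in config.populations:
            for i, seq in enumerate(genomes[pop.name]):
                write_fasta({f"{pop.name}_g{i}": seq}, outdir / f"{pop.name}_g{i}.fa")
        for gname, rds in reads.items():
            write_fastq(rds, outdir / f"{gname}.fq")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return {
        "reference": reference,
        "genomes": genomes,
        "truth": truth,
        "panel": panel,
        "reads": reads,
    }
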