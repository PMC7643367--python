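"""Pattern classification of catalog SVs, panel selection, enrichment, annotation.

Four pattern classes describe how a variant's *sequence* segregates between
population groups of Eurasian pigs:

* ``A-a``  (Asian-absence):  sequence in all European genomes, in no Asian one
* ``A-p``  (Asian-presence): sequence in all Asian genomes, in no European one
* ``SA-a`` (South-Asia-absence):  sequence in all non-South genomes, none South
* ``SA-p`` (South-Asia-presence): sequence in all South genomes, none non-South

Classification is strict all-or-none on the assembly panel; quantitative
deviation is measured downstream by the read-backed genotyper, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .asmdiff import SVCatalog, SVRecord

__all__ = [
    "GroupAssignment",
    "PatternCall",
    "PatternRegions",
    "EnrichmentResult",
    "classify_sv",
    "sequence_presence",
    "classify_catalog",
    "select_panel",
    "enrichment",
    "GeneModel",
    "region_annotate",
    "PATTERNS",
]

PATTERNS = ("A-a", "A-p", "SA-a", "SA-p")

ASIAN_GROUPS = frozenset({"ASIA_N", "ASIA_S", "TIBET"})
SOUTH_GROUPS = frozenset({"ASIA_S"})


@dataclass
class GroupAssignment:
    """Genome → group map plus the derived group sets used by the patterns.

    The crossbreed group (CROSS) sides with South Asia by default, reflecting
    minipig crossbreeds whose study region is South-Asian derived; set
    ``cross_with_south=False`` to keep it out of the South set. OUTGROUP
    genomes never enter any pattern comparison.
    """

    genome_to_group: dict[str, str]
    cross_with_south: bool = True
    cross_in_asian: bool = True

    def __post_init__(self) -> None:
        bad = {g for g, grp in self.genome_to_group.items() if grp not in
               {"EUR", "ASIA_N", "ASIA_S", "TIBET", "CROSS", "OUTGROUP"}}
        if bad:
            raise ValueError(f"unknown group for genomes: {sorted(bad)}")

    def _members(self, groups: frozenset[str]) -> frozenset[str]:
        return frozenset(g for g, grp in self.genome_to_group.items() if grp in groups)

    @property
    def european_set(self) -> frozenset[str]:
        return self._members(frozenset({"EUR"}))

    @property
    def asian_set(self) -> frozenset[str]:
        groups = set(ASIAN_GROUPS)
        if self.cross_in_asian:
            groups.add("CROSS")
        return self._members(frozenset(groups))

    @property
    def south_set(self) -> frozenset[str]:
        groups = set(SOUTH_GROUPS)
        if self.cross_with_south:
            groups.add("CROSS")
        return self._members(frozenset(groups))

    @property
    def non_south_set(self) -> frozenset[str]:
        return (self.european_set | self.asian_set) - self.south_set

    @classmethod
    def from_yaml(cls, path) -> "GroupAssignment":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        mapping = raw["genomes"] if "genomes" in raw else raw
        return cls(
            dict(mapping),
            cross_with_south=raw.get("cross_with_south", True) if isinstance(raw, dict) else True,
        )


@dataclass(frozen=True)
class PatternCall:
    sv_id: str
    pattern: str  # one of PATTERNS or "none"


@dataclass(frozen=True)
class PatternRegions:
    """The two X-chromosome windows the patterns live in (half-open bp)."""

    window_SA: tuple[int, int]
    window_A: tuple[int, int]
    min_panel_len: int = 100

    def __post_init__(self) -> None:
        for lo, hi in (self.window_SA, self.window_A):
            if lo >= hi:
                raise ValueError("windows must be half-open non-empty intervals")
        if max(self.window_SA[0], self.window_A[0]) < min(self.window_SA[1], self.window_A[1]):
            raise ValueError("windows must not overlap")


# the two window parameterizations used in the study region (Mb-scale, on X):
# the wider pair from the detection protocol and the tighter pair from the
# observed enrichment
REGION_PRESETS = {
    "methods": PatternRegions((44_000_000, 58_000_000), (58_000_000, 92_000_000)),
    "results": PatternRegions((45_000_000, 57_000_000), (57_000_000, 87_000_000)),
}


def classify_sv(
    presence_row: Mapping[str, bool],
    groups: GroupAssignment,
    sv_id: str = "",
    sa_precedence: bool = True,
) -> PatternCall:
    """Label one SV's *sequence*-presence row with its pattern.

    ``presence_row`` maps genome name → whether that genome carries the
    variant sequence (see :func:`sequence_presence` for converting catalog
    call-presence rows). When an SV satisfies both an SA and an A pattern,
    SA wins by default (``sa_precedence``).
    """
    eur, asia = groups.european_set, groups.asian_set
    south, non_south = groups.south_set, groups.non_south_set
    missing = (eur | asia) - set(presence_row)
    if missing:
        raise ValueError(f"genomes missing from presence row: {sorted(missing)}")

    def all_of(gs):  # noqa: ANN001 - tiny closures over the row
        return bool(gs) and all(presence_row[g] for g in gs)

    def none_of(gs):
        return all(not presence_row[g] for g in gs)

    sa = None
    if all_of(non_south) and none_of(south):
        sa = "SA-a"
    elif all_of(south) and none_of(non_south):
        sa = "SA-p"
    a = None
    if all_of(eur) and none_of(asia):
        a = "A-a"
    elif all_of(asia) and none_of(eur):
        a = "A-p"
    order = (sa, a) if sa_precedence else (a, sa)
    for label in order:
        if label:
            return PatternCall(sv_id, label)
    return PatternCall(sv_id, "none")


def sequence_presence(catalog: SVCatalog) -> pd.DataFrame:
    """Genome × SV matrix of *sequence* presence.

    The catalog's presence matrix marks where the SV was *called* against the
    reference. For insertions the inserted sequence is present exactly in the
    calling genomes; for deletions (and indels) the reference segment is
    present in the genomes where the SV was NOT called, so those columns are
    inverted.
    """
    seq_pres = catalog.presence.copy()
    for i, rec in enumerate(catalog.records):
        if rec.type != "insertion":
            col = f"sv{i}"
            seq_pres[col] = ~seq_pres[col]
    return seq_pres


def classify_catalog(
    catalog: SVCatalog,
    groups: GroupAssignment,
    include_indels: bool = False,
    sa_precedence: bool = True,
) -> list[PatternCall]:
    """classify_sv over every catalog record (sequence-presence semantics).

    ``indel``-type records are excluded by default: their call does not state
    cleanly which sequence is present where.
    """
    seq_pres = sequence_presence(catalog)
    calls = []
    for i, rec in enumerate(catalog.records):
        sv_id = f"sv{i}"
        if rec.type == "indel" and not include_indels:
            calls.append(PatternCall(sv_id, "none"))
            continue
        row = seq_pres[sv_id].to_dict()
        calls.append(classify_sv(row, groups, sv_id, sa_precedence))
    return calls


def select_panel(
    calls: Sequence[PatternCall],
    catalog: SVCatalog,
    regions: PatternRegions | None = None,
    apply_window_filter: bool = True,
) -> list[tuple[PatternCall, SVRecord]]:
    """Retain pattern SVs larger than the panel cutoff, inside their window.

    Size is strict (> ``min_panel_len``). SA-pattern SVs must lie inside
    ``window_SA`` and A-pattern SVs inside ``window_A`` (an SV "lies inside"
    if its reference start does); window filtering can be switched off for
    genome-wide panels.
    """
    min_len = regions.min_panel_len if regions is not None else 100
    out = []
    by_id = {f"sv{i}": rec for i, rec in enumerate(catalog.records)}
    for call in calls:
        if call.pattern == "none":
            continue
        rec = by_id[call.sv_id]
        if rec.length <= min_len:
            continue
        if apply_window_filter and regions is not None:
            lo, hi = regions.window_SA if call.pattern.startswith("SA") else regions.window_A
            if not (lo <= rec.ref_start < hi):
                continue
        out.append((call, rec))
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    chrom: str
    observed: int
    expected: float
    chi2: float
    p: float


def enrichment(
    calls: Sequence[PatternCall],
    catalog: SVCatalog,
    chrom: str,
) -> EnrichmentResult:
    """1-df goodness-of-fit test of pattern-SV concentration on one chromosome.

    The null expectation is proportional to the chromosome's share of ALL
    catalog SVs (a per-SV, not per-bp, null). chi2 = sum (obs-exp)^2/exp over
    the on/off-chromosome split; p is the upper chi-square tail.
    """
    if not catalog.records:
        raise ValueError("empty catalog")
    total_catalog = len(catalog.records)
    on_catalog = sum(1 for r in catalog.records if r.chrom == chrom)
    pattern_ids = {c.sv_id for c in calls if c.pattern != "none"}
    total_pat = len(pattern_ids)
    by_id = {f"sv{i}": rec for i, rec in enumerate(catalog.records)}
    on_pat = sum(1 for sid in pattern_ids if by_id[sid].chrom == chrom)
    frac = on_catalog / total_catalog
    exp_on = total_pat * frac
    exp_off = total_pat * (1 - frac)
    if exp_on == 0 or exp_off == 0:
        raise ValueError("zero expected count; cannot test")
    chi2 = (on_pat - exp_on) ** 2 / exp_on + ((total_pat - on_pat) - exp_off) ** 2 / exp_off
    p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(chrom, on_pat, exp_on, float(chi2), max(p, 5e-324))


# ---------------------------------------------------------------------------
# lightweight region annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One transcript's exon structure (half-open intervals on the reference)."""

    gene: str
    transcript: str
    chrom: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for lo, hi in self.exons:
            if lo >= hi:
                raise ValueError(f"malformed exon interval ({lo},{hi}) in {self.transcript}")

    @property
    def span(self) -> tuple[int, int]:
        return (min(lo for lo, _ in self.exons), max(hi for _, hi in self.exons))


def _interval(rec: SVRecord) -> tuple[int, int]:
    # an insertion point is treated as a 1-bp interval
    if rec.ref_end == rec.ref_start:
        return (rec.ref_start, rec.ref_start + 1)
    return (rec.ref_start, rec.ref_end)


def region_annotate(
    panel: Sequence[tuple[PatternCall, SVRecord]],
    gene_models: Sequence[GeneModel],
) -> tuple[dict[str, str], dict[str, int]]:
    """Label each panel SV exonic / intronic / intergenic; count SVs per gene.

    Returns (sv_id → label, gene → SV count restricted to genes hit by >= 2
    SVs). Labels partition the panel: exonic beats intronic beats intergenic.
    """
    labels: dict[str, str] = {}
    gene_hits: dict[str, set[str]] = {}
    for call, rec in panel:
        lo, hi = _interval(rec)
        label = "intergenic"
        for gm in gene_models:
            if gm.chrom != rec.chrom:
                continue
            glo, ghi = gm.span
            if hi <= glo or lo >= ghi:
                continue
            if any(hi > elo and lo < ehi for elo, ehi in gm.exons):
                label = "exonic"
                gene_hits.setdefault(gm.gene, set()).add(call.sv_id)
                break
            label = "intronic"
            gene_hits.setdefault(gm.gene, set()).add(call.sv_id)
        labels[call.sv_id] = label
    multi = {g: len(ids) for g, ids in gene_hits.items() if len(ids) >= 2}
    return labels, multi


def read_gene_models_bed12(path) -> list[GeneModel]:
    """Parse a BED12 file into gene models (name field = gene:transcript)."""
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            name = f[3]
            gene, _, transcript = name.partition(":")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            models.append(GeneModel(gene, transcript or gene, chrom, exons))
    return models
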