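"""Origination intervals, introgression flags, and haplogroup scenarios.

A presence/absence marker that arose once and was never lost must have
originated on the stem edge of the clade of its carriers: its origination
interval is (age of the carrier clade's parent node, age of its crown node).
Carrier sets that are NOT a clade need more than one gain under the
gains-only model; the minimal gain count and the gain edges flag candidate
introgression (or homoplasy).

The scenario engine replays qualitative haplogroup history at two linked
X-chromosome loci (alleles A1/A2 and B1/B2): population splits copy haplotype
sets, fixation replaces them, admixture-with-recombination expands a
population to all recombinant combinations of the available alleles, and
selection keeps only haplotypes carrying a favored allele. Everything is
deterministic set algebra.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import dendropy
import yaml

__all__ = [
    "DatedTree",
    "CarrierProfile",
    "OriginInterval",
    "Haplogroup",
    "Scenario",
    "Phase",
    "Event",
    "origination_interval",
    "min_origins",
    "enumerate_recombinants",
    "simulate_phases",
    "load_dated_tree",
    "default_sus_tree",
    "default_fig_scenario",
    "NonMonophyleticError",
]


class NonMonophyleticError(ValueError):
    """Carriers do not form a clade; use min_origins for multi-gain analysis."""


@dataclass
class DatedTree:
    """A rooted tree whose internal nodes carry divergence ages in Ma.

    Leaves have age 0. Ages must strictly decrease root -> tip (ultrametricity
    is not required). Wraps a dendropy tree read from newick where internal
    node labels are the ages.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                node.age_ma = 0.0
            else:
                label = node.label if node.label is not None else (
                    node.taxon.label if node.taxon else None
                )
                if label is None:
                    raise ValueError("internal node without an age label")
                node.age_ma = float(label)
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None and node.parent_node.age_ma <= node.age_ma and not node.is_leaf():
                raise ValueError("ages must strictly decrease root -> tip")

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def mrca(self, names: Iterable[str]):
        taxa = [self.tree.taxon_namespace.get_taxon(n) for n in names]
        missing = [n for n, t in zip(names, taxa) if t is None]
        if missing:
            raise ValueError(f"unknown leaves: {missing}")
        return self.tree.mrca(taxa=taxa)

    def restrict(self, names: Iterable[str]) -> "DatedTree":
        """Subtree induced by the given leaves (ages preserved)."""
        clone = dendropy.Tree(self.tree)
        keep = set(names)
        clone.retain_taxa_with_labels(sorted(keep))
        # dendropy keeps internal labels on retained nodes; suppressed
        # unifurcations collapse toward the root, keeping the deepest label
        return DatedTree(clone)


def load_dated_tree(source: str | Path) -> DatedTree:
    """Read a newick tree whose internal node labels are ages in Ma."""
    text = str(source)
    if "(" not in text:  # a path rather than newick text
        text = Path(source).read_text()
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = True
    return DatedTree(tree)


def default_sus_tree() -> DatedTree:
    """The packaged dated pig phylogeny (ages in Ma on internal nodes)."""
    text = resources.files("introscan.data").joinpath("sus_scrofa_dated.nwk").read_text()
    return load_dated_tree(text)


@dataclass
class CarrierProfile:
    """leaf -> {carrier, non-carrier, unknown}."""

    states: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.states.values() if v not in ("carrier", "non-carrier", "unknown")}
        if bad:
            raise ValueError(f"bad states: {sorted(bad)}")

    @property
    def carriers(self) -> set[str]:
        return {k for k, v in self.states.items() if v == "carrier"}

    @classmethod
    def from_carriers(cls, carriers: Iterable[str], all_leaves: Iterable[str],
                      unknown: Iterable[str] = ()) -> "CarrierProfile":
        carriers, unknown = set(carriers), set(unknown)
        states = {}
        for leaf in all_leaves:
            if leaf in carriers:
                states[leaf] = "carrier"
            elif leaf in unknown:
                states[leaf] = "unknown"
            else:
                states[leaf] = "non-carrier"
        return cls(states)


@dataclass(frozen=True)
class OriginInterval:
    older_bound: float  # Ma
    younger_bound: float

    def __post_init__(self) -> None:
        if not self.older_bound >= self.younger_bound >= 0:
            raise ValueError("require older >= younger >= 0")


def origination_interval(tree: DatedTree, profile: CarrierProfile) -> OriginInterval:
    """(parent age, crown age) of the carrier clade under single origin, no loss.

    Leaves marked ``unknown`` are ignored when checking monophyly. A single
    carrier leaf has crown age 0. A root-spanning carrier set returns the
    root's age as the older bound (no older calibration exists on the tree).
    """
    carriers = profile.carriers
    if not carriers:
        raise ValueError("at least one carrier required")
    unknown = {k for k, v in profile.states.items() if v == "unknown"}
    mrca = tree.mrca(sorted(carriers))
    under = {lf.taxon.label for lf in mrca.leaf_iter()}
    informative = under - unknown
    if informative - carriers:
        raise NonMonophyleticError(
            "carriers are not monophyletic on this tree; run min_origins to "
            f"locate the gains (non-carriers inside the clade: {sorted(informative - carriers)})"
        )
    crown = float(mrca.age_ma)
    parent = mrca.parent_node
    older = float(parent.age_ma) if parent is not None else float(mrca.age_ma)
    return OriginInterval(older, crown)


def min_origins(tree: DatedTree, profile: CarrierProfile) -> tuple[int, list[tuple[float, float]]]:
    """Minimal number of gains (losses disallowed) and their edges.

    With losses forbidden, a gain on an edge makes every leaf below it a
    carrier, so the optimum is one gain on the stem of each maximal
    carrier-only subtree (``unknown`` leaves are free to go either way).
    Returns the gain count and the gain edges as (parent age, child age)
    pairs sorted oldest first.
    """
    carriers = profile.carriers
    if not carriers:
        raise ValueError("at least one carrier required")

    # bottom-up: a node is "all-carrier" if every informative leaf below is a
    # carrier and at least one is (unknown-only subtrees stay neutral)
    gain_edges: list[tuple[float, float]] = []

    def status(node) -> str:  # "carrier" | "non" | "neutral"
        if node.is_leaf():
            return {
                "carrier": "carrier",
                "non-carrier": "non",
                "unknown": "neutral",
            }[profile.states.get(node.taxon.label, "non-carrier")]
        child_status = [status(c) for c in node.child_nodes()]
        if all(s in ("carrier", "neutral") for s in child_status) and any(
            s == "carrier" for s in child_status
        ):
            return "carrier"
        # emit a gain for every maximal carrier child subtree
        for c, s in zip(node.child_nodes(), child_status):
            if s == "carrier":
                gain_edges.append((float(node.age_ma), float(c.age_ma)))
        return "non" if any(s == "non" for s in child_status) else "neutral"

    root = tree.tree.seed_node
    root_status = status(root)
    if root_status == "carrier":
        gain_edges.append((float(root.age_ma), float(root.age_ma)))
    gain_edges.sort(key=lambda e: (-e[0], -e[1]))
    return len(gain_edges), gain_edges


# ---------------------------------------------------------------------------
# haplogroup scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Haplogroup:
    """One haplotype over the two pattern loci."""

    locus_A: str  # A1 | A2
    locus_B: str  # B1 | B2

    def __post_init__(self) -> None:
        if self.locus_A not in ("A1", "A2") or self.locus_B not in ("B1", "B2"):
            raise ValueError(f"bad haplogroup {self.locus_A}{self.locus_B}")

    def __str__(self) -> str:
        return f"{self.locus_A}{self.locus_B}"

    @classmethod
    def parse(cls, text: str) -> "Haplogroup":
        return cls(text[:2], text[2:])


def enumerate_recombinants(alleles_A: set[str], alleles_B: set[str]) -> set[Haplogroup]:
    """All recombinant haplotypes: the Cartesian product of the allele sets."""
    if not alleles_A or not alleles_B:
        raise ValueError("both allele sets must be non-empty")
    return {Haplogroup(a, b) for a, b in itertools.product(alleles_A, alleles_B)}


@dataclass(frozen=True)
class Event:
    """One scenario event.

    kind: split | fix | admix | select
      split: pop -> (daughter1, daughter2) at time_ma
      fix: pop's haplotype set replaced by ``haplotypes``
      admix: source -> target; with recombination the target becomes all
             recombinants of the union's alleles, without it the plain union
      select: keep only target-pop haplotypes carrying ``favored`` at ``locus``
    """

    kind: str
    pop: str = ""
    daughters: tuple[str, str] = ("", "")
    time_ma: Optional[float] = None
    haplotypes: tuple[str, ...] = ()
    source: str = ""
    target: str = ""
    recombination: bool = True
    locus: str = ""
    favored: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("split", "fix", "admix", "select"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class Phase:
    name: str
    events: list[Event] = field(default_factory=list)


@dataclass
class Scenario:
    phases: list[Phase]

    def __post_init__(self) -> None:
        times = [
            e.time_ma
            for ph in self.phases
            for e in ph.events
            if e.time_ma is not None
        ]
        if any(t2 > t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-increasing across the scenario")

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "Scenario":
        phases = []
        for ph in raw["phases"]:
            events = []
            for ev in ph.get("events", []):
                ev = dict(ev)
                if "daughters" in ev:
                    ev["daughters"] = tuple(ev["daughters"])
                if "haplotypes" in ev:
                    ev["haplotypes"] = tuple(ev["haplotypes"])
                events.append(Event(**ev))
            phases.append(Phase(ph["name"], events))
        return cls(phases)


def _apply_event(pops: dict[str, set[Haplogroup]], ev: Event) -> None:
    if ev.kind == "split":
        if ev.pop not in pops:
            raise ValueError(f"split: unknown population {ev.pop!r}")
        haps = pops.pop(ev.pop)
        d1, d2 = ev.daughters
        pops[d1] = set(haps)
        pops[d2] = set(haps)
    elif ev.kind == "fix":
        if ev.pop not in pops:
            raise ValueError(f"fix: unknown population {ev.pop!r}")
        pops[ev.pop] = {Haplogroup.parse(h) for h in ev.haplotypes}
    elif ev.kind == "admix":
        for p in (ev.source, ev.target):
            if p not in pops:
                raise ValueError(f"admix: unknown population {p!r}")
        union = pops[ev.source] | pops[ev.target]
        if ev.recombination:
            pops[ev.target] = enumerate_recombinants(
                {h.locus_A for h in union}, {h.locus_B for h in union}
            )
        else:
            pops[ev.target] = union
    elif ev.kind == "select":
        if ev.pop not in pops:
            raise ValueError(f"select: unknown population {ev.pop!r}")
        kept = {h for h in pops[ev.pop] if getattr(h, f"locus_{ev.locus}") == ev.favored}
        if not kept:
            raise ValueError(
                f"selection for {ev.favored} at locus {ev.locus} removes every "
                f"haplotype from {ev.pop}"
            )
        pops[ev.pop] = kept


def simulate_phases(
    scenario: Scenario,
    initial: Mapping[str, Iterable[Haplogroup | str]],
) -> dict:
    """Deterministically evolve haplotype sets through the scenario phases.

    Returns ``{"phases": [{"name", "populations": {pop: sorted haplotype
    strings}}], "final": {...}, "census": int}`` where census counts distinct
    haplogroups across all populations extant at the end.
    """
    pops: dict[str, set[Haplogroup]] = {
        p: {h if isinstance(h, Haplogroup) else Haplogroup.parse(h) for h in haps}
        for p, haps in initial.items()
    }
    history = []
    for phase in scenario.phases:
        steps = []
        for ev in phase.events:
            _apply_event(pops, ev)
            steps.append(
                {
                    "event": ev.kind,
                    "populations": {
                        p: sorted(str(h) for h in haps) for p, haps in sorted(pops.items())
                    },
                }
            )
        history.append(
            {
                "name": phase.name,
                "steps": steps,
                "populations": {p: sorted(str(h) for h in haps) for p, haps in sorted(pops.items())},
            }
        )
    distinct = set().union(*pops.values()) if pops else set()
    return {
        "phases": history,
        "final": {p: sorted(str(h) for h in haps) for p, haps in sorted(pops.items())},
        "census": len(distinct),
    }


def default_fig_scenario() -> tuple[Scenario, dict[str, set[Haplogroup]]]:
    """The packaged four-phase Eurasian haplogroup scenario.

    Phase 1: one ancestral Eurasian population, undifferentiated (A1B1 stands
    for the ancestral state at both loci).
    Phase 2 (1-0.6 Ma): Europe and Asia diverge; the low-recombination window
    fixes alternative haplotypes A1B1 (Europe) and A2B2 (Asia).
    Phase 3 (0.5-0.2 Ma): South and North Asia split; European boars reach
    North Asia and admix with recombination (four recombinant haplotypes),
    then cold-adaptation selection at locus A keeps only A1 carriers.
    Phase 4 (~0.2 Ma): Tibet splits from North Asia and fixes A1B2.
    """
    scenario = Scenario(
        phases=[
            Phase("phase1_ancestral", []),
            Phase(
                "phase2_divergence",
                [
                    Event("split", pop="Eurasia", daughters=("Europe", "Asia"), time_ma=1.0),
                    Event("fix", pop="Europe", haplotypes=("A1B1",)),
                    Event("fix", pop="Asia", haplotypes=("A2B2",)),
                ],
            ),
            Phase(
                "phase3_admixture_selection",
                [
                    Event("split", pop="Asia", daughters=("South-Asia", "North-Asia"), time_ma=0.6),
                    Event("admix", source="Europe", target="North-Asia", recombination=True),
                    Event("select", pop="North-Asia", locus="A", favored="A1"),
                ],
            ),
            Phase(
                "phase4_tibet",
                [
                    Event("split", pop="North-Asia", daughters=("Tibet", "North-Asia"), time_ma=0.2),
                    Event("fix", pop="Tibet", haplotypes=("A1B2",)),
                ],
            ),
        ]
    )
    initial = {"Eurasia": {Haplogroup("A1", "B1")}}
    return scenario, initial
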