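"""Herb–ingredient–target (HIT) network assembly.

A traditional-medicine formula is a set of herbs; each herb contributes
chemical compounds, and each compound is annotated with human gene targets.
Compounds are screened on two ADME descriptors — oral bioavailability (OB, %)
and drug-likeness (DL, unitless) — and the surviving compounds, their herbs and
their targets form a tripartite herb→compound→target graph.  The formula's
pooled targets are then intersected with disease genes collated from several
curated databases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "CompoundRecord",
    "DiseaseGeneSource",
    "filter_adme",
    "normalize_gene_symbols",
    "collate_disease_genes",
    "intersect_targets",
    "build_hit_network",
    "herb_target_share",
    "combined_target_coverage",
]

#: Inclusive ADME cutoffs used to declare a compound "active".
DEFAULT_OB_MIN = 20.0
DEFAULT_DL_MIN = 0.18


@dataclass
class CompoundRecord:
    """One herb compound with its ADME descriptors and target annotations.

    Parameters
    ----------
    herb_id : str
        Short herb label (e.g. ``Mf``, ``Zr``, ``Ar``, ``CRr``, ``CPr``, ``Pp``).
    compound_id : str
        Compound identifier; compounds shared by several herbs reuse the id.
    compound_name : str
        Human-readable compound name.
    ob : float
        Oral bioavailability, percent, ``>= 0``.
    dl : float
        Drug-likeness, unitless, ``>= 0``.
    targets : set of str
        Normalized gene symbols the compound is annotated to act on.
    """

    herb_id: str
    compound_id: str
    compound_name: str
    ob: float
    dl: float
    targets: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.ob < 0 or self.dl < 0:
            raise ValueError(
                f"compound {self.herb_id}/{self.compound_id} "
                f"({self.compound_name}): OB and DL must be non-negative, "
                f"got ob={self.ob}, dl={self.dl}"
            )
        if any(not t for t in self.targets):
            raise ValueError(
                f"compound {self.herb_id}/{self.compound_id}: empty target symbol"
            )


@dataclass
class DiseaseGeneSource:
    """A named disease-gene database pull (e.g. GeneCards, OMIM, TTD)."""

    source_name: str
    genes: set[str]


def filter_adme(
    records: Iterable[CompoundRecord],
    ob_min: float = DEFAULT_OB_MIN,
    dl_min: float = DEFAULT_DL_MIN,
) -> list[CompoundRecord]:
    """Keep compounds with ``ob >= ob_min`` and ``dl >= dl_min``.

    Both cutoffs are inclusive, so a compound sitting exactly on the
    OB = 20%, DL = 0.18 boundary is retained.  Input order is preserved and
    the operation is idempotent.
    """
    records = list(records)
    for r in records:  # validation also triggers for dicts built by hand
        if r.ob < 0 or r.dl < 0:
            raise ValueError(
                f"compound {r.herb_id}/{r.compound_id}: negative OB or DL"
            )
    return [r for r in records if r.ob >= ob_min and r.dl >= dl_min]


def normalize_gene_symbols(raw: Iterable[str]) -> set[str]:
    """Trim whitespace, uppercase, drop empties and duplicates.

    No alias resolution is attempted: symbols are taken at face value after
    case/whitespace collapse (see the methods note for the limitation).
    """
    out = set()
    for s in raw:
        s = s.strip().upper()
        if s:
            out.add(s)
    return out


def collate_disease_genes(
    sources: Iterable[DiseaseGeneSource],
) -> tuple[set[str], dict[frozenset[str], int]]:
    """Pool disease genes from several sources and tabulate Venn regions.

    Returns
    -------
    union : set of str
        Set-union of all source gene sets.
    region_counts : dict
        For every non-empty subset of source names, the number of genes that
        belong to *exactly* those sources.  Counts over all regions sum to
        ``len(union)``.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("need at least one disease-gene source")
    names = [s.source_name for s in sources]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate source names in {names}")

    union: set[str] = set().union(*(s.genes for s in sources))
    membership: dict[str, set[str]] = {g: set() for g in union}
    for s in sources:
        for g in s.genes:
            membership[g].add(s.source_name)

    # every non-empty subset, including empty regions, so the table is a
    # complete Venn tabulation
    from itertools import combinations

    region_counts: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            region_counts[frozenset(combo)] = 0
    for g, mem in membership.items():
        region_counts[frozenset(mem)] += 1
    return union, region_counts


def intersect_targets(gczx_targets: set[str], disease_genes: set[str]) -> set[str]:
    """Shared genes between the formula's pooled targets and the disease set."""
    return set(gczx_targets) & set(disease_genes)


HERB, COMPOUND, TARGET = "herb", "compound", "target"


def build_hit_network(
    records: Iterable[CompoundRecord], keep_targets: set[str]
) -> nx.Graph:
    """Build the tripartite herb–compound–target graph.

    Nodes carry a ``layer`` attribute (``herb`` | ``compound`` | ``target``).
    Targets outside ``keep_targets`` are discarded; compounds left with no
    retained target and herbs left with no compound are pruned, so the graph
    never contains a dangling inner node.  A compound occurring in several
    herbs becomes a single node with one edge per parent herb.
    """
    g = nx.Graph()
    for r in records:
        kept = r.targets & keep_targets
        if not kept:
            continue
        g.add_node(r.herb_id, layer=HERB)
        g.add_node(r.compound_id, layer=COMPOUND, name=r.compound_name)
        g.add_edge(r.herb_id, r.compound_id)
        for t in kept:
            g.add_node(t, layer=TARGET)
            g.add_edge(r.compound_id, t)
    if g.number_of_nodes() == 0:
        warnings.warn("HIT network is empty after target restriction")
    return g


def _layer_nodes(net: nx.Graph, layer: str) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d.get("layer") == layer]


def _herb_targets(net: nx.Graph, herb: str) -> set[str]:
    out: set[str] = set()
    for comp in net.neighbors(herb):
        for t in net.neighbors(comp):
            if net.nodes[t]["layer"] == TARGET:
                out.add(t)
    return out


def herb_target_share(net: nx.Graph) -> dict[str, tuple[int, float]]:
    """Per-herb reachable-target counts and fractions of the pooled target set.

    Fractions are relative to the union of all targets in the network, so they
    may sum above 1 when herbs share targets.  The union coverage of all herbs
    together is exactly 1.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty HIT network")
    all_targets = set(_layer_nodes(net, TARGET))
    out: dict[str, tuple[int, float]] = {}
    for herb in _layer_nodes(net, HERB):
        t = _herb_targets(net, herb)
        out[herb] = (len(t), len(t) / len(all_targets))
    return out


def combined_target_coverage(net: nx.Graph, herbs: Iterable[str]) -> float:
    """Fraction of the pooled target set reachable from a subset of herbs."""
    all_targets = set(_layer_nodes(net, TARGET))
    covered: set[str] = set()
    for herb in herbs:
        covered |= _herb_targets(net, herb)
    return len(covered) / len(all_targets)
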