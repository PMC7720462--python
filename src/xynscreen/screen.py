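"""Trait-enriched clade detection and representative selection.

Leaves of the family tree are tagged with extremophily traits derived from
the source organism's genus — putative thermostable (Tr), alkalophilic (Ak)
and acidophilic (Ac).  The screen then reports well-supported clades
enriched for a target trait combination (by default Tr+Ak: candidates for
hot, alkaline process conditions) and picks representative sequences that
cover as many distinct domain architectures as possible, favouring the most
divergent member of each architecture.

Thresholds formalise what a practitioner judges on the published cladogram:
bootstrap support at least 50 (lower values are conventionally
non-significant), trait purity at least 0.6, clade size at least 3.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .phylo import Node, PhyloTree

logger = logging.getLogger("xynscreen.screen")

TRAITS = ("Tr", "Ak", "Ac")

#: Genus-level trait assignments for the genera relevant to the family's
#: alkaline-thermophile clusters and their acidophilic counterparts.
DEFAULT_TRAIT_MAP: dict[str, frozenset[str]] = {
    "Bacillus": frozenset({"Tr", "Ak"}),
    "Thermobacillus": frozenset({"Tr", "Ak"}),
    "Geobacillus": frozenset({"Tr", "Ak"}),
    "Dictyoglomus": frozenset({"Tr", "Ak"}),
    "Caldicellulosiruptor": frozenset({"Tr", "Ak"}),
    "Thermopolyspora": frozenset({"Tr"}),
    "Thermobifida": frozenset({"Tr"}),
    "Halorhabdus": frozenset({"Tr", "Ak"}),
    "Nesterenkonia": frozenset(),
    "Jonesia": frozenset(),
}


class AnnotationError(ValueError):
    pass


@dataclass
class CandidateCluster:
    """A supported clade enriched for the target traits."""

    leaf_ids: frozenset[str]
    support: int
    purity: dict[str, float]        # per target trait
    combined_purity: float          # fraction of leaves with ALL target traits
    da_diversity: int = 0
    representatives: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.leaf_ids)


def read_trait_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read ``genus <tab> comma-separated-traits`` (empty trait field ok)."""
    out: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("genus"):
            raise ValueError("trait table must start with a 'genus' header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            genus = parts[0]
            traits = frozenset(t for t in (parts[1].split(",") if len(parts) > 1 and parts[1] else []) if t)
            bad = traits - set(TRAITS)
            if bad:
                raise ValueError(f"{genus}: unknown traits {sorted(bad)}")
            out[genus] = traits
    return out


def annotate_traits(
    tree: PhyloTree,
    taxonomy: dict[str, tuple[str, str]] | dict[str, str],
    trait_map: dict[str, frozenset[str]],
) -> dict[str, frozenset[str]]:
    """Map each leaf to its genus's trait set (empty if the genus is not in
    the map).  Raises when leaves are missing from the taxonomy."""
    def genus_of(v) -> str:
        return v[0] if isinstance(v, tuple) else v

    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in taxonomy]
    if missing:
        raise AnnotationError(f"leaves missing from taxonomy: {sorted(missing)}")
    out: dict[str, frozenset[str]] = {}
    unmapped: set[str] = set()
    for leaf in leaves:
        genus = genus_of(taxonomy[leaf])
        if genus not in trait_map:
            unmapped.add(genus)
        out[leaf] = trait_map.get(genus, frozenset())
    if unmapped:
        logger.info("genera without trait assignment: %s", sorted(unmapped))
    return out


def _candidate_clades(
    tree: PhyloTree, outgroup: str | None = None
) -> list[tuple[frozenset[str], int]]:
    """Enumerate candidate clades with their defining-edge supports.

    Rooted trees contribute each internal node's leaf set.  Unrooted trees
    (trifurcating root) are handled through bipartitions: the clade is the
    side not containing the outgroup (or the smaller side when none is
    given).  The full leaf set is always a trivially supported candidate.
    """
    all_leaves = frozenset(tree.leaf_names())
    sets = tree.leafsets()
    out: list[tuple[frozenset[str], int]] = [(all_leaves, 100)]
    unrooted = len(tree.root.children) > 2
    for node in tree.postorder():
        if node is tree.root or node.is_leaf:
            continue
        side = sets[id(node)]
        support = node.support if node.support is not None else 0
        if unrooted:
            other = all_leaves - side
            if outgroup is not None:
                clade = side if outgroup not in side else other
            else:
                clade = min(side, other, key=lambda s: (len(s), sorted(s)))
            out.append((clade, support))
        else:
            out.append((side, support))
    return out


def find_candidate_clusters(
    tree: PhyloTree,
    leaf_traits: dict[str, frozenset[str]],
    target: frozenset[str] = frozenset({"Tr", "Ak"}),
    support_min: int = 50,
    purity_min: float = 0.6,
    min_cluster_size: int = 3,
    mode: str = "all",
    das: dict[str, str] | None = None,
    outgroup: str | None = None,
) -> list[CandidateCluster]:
    """Maximal well-supported clades enriched for the target traits.

    A clade qualifies when its defining-edge support is at least
    ``support_min``, it has at least ``min_cluster_size`` leaves, and the
    fraction of leaves carrying the target traits (all of them in mode
    "all", at least one in mode "any") is at least ``purity_min``.  Among
    qualifying clades, only maximal ones (not nested inside another
    qualifying clade) are reported, sorted by (purity product over target
    traits, size) descending.
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    target = frozenset(target)
    passing: list[tuple[frozenset[str], int]] = []
    for clade, support in _candidate_clades(tree, outgroup):
        if len(clade) < min_cluster_size or support < support_min:
            continue
        if mode == "all":
            positive = sum(1 for l in clade if target <= leaf_traits.get(l, frozenset()))
        else:
            positive = sum(1 for l in clade if target & leaf_traits.get(l, frozenset()))
        if target and positive / len(clade) < purity_min:
            continue
        if not target:
            continue
        passing.append((clade, support))

    # maximality: keep clades not nested inside another passing clade
    passing.sort(key=lambda cs: -len(cs[0]))
    kept: list[tuple[frozenset[str], int]] = []
    for clade, support in passing:
        if any(clade < other for other, _ in kept):
            continue
        if any(clade == other for other, _ in kept):
            continue
        kept.append((clade, support))

    clusters: list[CandidateCluster] = []
    for clade, support in kept:
        purity = {
            t: sum(1 for l in clade if t in leaf_traits.get(l, frozenset())) / len(clade)
            for t in sorted(target)
        }
        combined = sum(1 for l in clade
                       if target <= leaf_traits.get(l, frozenset())) / len(clade)
        diversity = len({das[l] for l in clade}) if das else 0
        clusters.append(CandidateCluster(
            leaf_ids=clade, support=support, purity=purity,
            combined_purity=combined, da_diversity=diversity,
        ))
    def purity_product(c: CandidateCluster) -> float:
        out = 1.0
        for t in sorted(target):
            out *= c.purity[t]
        return out

    clusters.sort(key=lambda c: (-purity_product(c), -c.size, sorted(c.leaf_ids)))
    return clusters


def select_representatives(
    cluster: CandidateCluster,
    das: dict[str, str],
    k: int,
    tree: PhyloTree | None = None,
) -> list[str]:
    """Pick up to ``k`` DA-diverse representatives from a cluster.

    Architectures are visited by descending frequency in the cluster; within
    an architecture, the leaf with the longest terminal branch (most
    divergent) wins, ties by id.  Rounds repeat over architectures until
    ``k`` ids are chosen or the cluster is exhausted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    term_len: dict[str, float] = {}
    if tree is not None:
        for node in tree.postorder():
            if node.is_leaf:
                term_len[node.name] = node.length or 0.0
    members = sorted(cluster.leaf_ids)
    counts = Counter(das[l] for l in members)
    by_da: dict[str, list[str]] = {}
    for l in members:
        by_da.setdefault(das[l], []).append(l)
    for da in by_da:
        by_da[da].sort(key=lambda l: (-term_len.get(l, 0.0), l))
    da_order = sorted(counts, key=lambda d: (-counts[d], d))
    chosen: list[str] = []
    round_i = 0
    while len(chosen) < min(k, len(members)):
        progressed = False
        for da in da_order:
            if len(chosen) >= min(k, len(members)):
                break
            pool = by_da[da]
            if round_i < len(pool):
                chosen.append(pool[round_i])
                progressed = True
        round_i += 1
        if not progressed:
            break
    return chosen


def write_cluster_report(
    clusters: list[CandidateCluster],
    path: str | Path,
    target: frozenset[str] = frozenset({"Tr", "Ak"}),
) -> None:
    """Tab-separated report: one row per cluster."""
    traits = sorted(target)
    with open(path, "w") as fh:
        cols = (["cluster", "support", "size"]
                + [f"purity_{t}" for t in traits]
                + ["combined_purity", "da_diversity", "representatives", "members"])
        fh.write("\t".join(cols) + "\n")
        for i, c in enumerate(clusters, start=1):
            row = [str(i), str(c.support), str(c.size)]
            row += [f"{c.purity.get(t, 0.0):.3f}" for t in traits]
            row += [f"{c.combined_purity:.3f}", str(c.da_diversity),
                    ",".join(c.representatives),
                    ",".join(sorted(c.leaf_ids))]
            fh.write("\t".join(row) + "\n")
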