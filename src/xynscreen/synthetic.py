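"""Synthetic glycoside-hydrolase family generator with known ground truth.

Real screens of this kind start from a database snapshot of family members
(sequences, Pfam domain hits, source taxonomy).  This module replaces that
download with a simulated family whose statistical structure matches what
the screening assumes: a phylogeny with trait-labelled clades planted on
it, catalytic domains evolved along the tree, per-kingdom domain
architecture composition (mostly the bare catalytic domain, a CBM-bearing
minority, a minority with unidentified C-terminal tails), and a domain-hit
table whose coordinates are consistent with the sequences — including a
configurable fraction of sub-threshold hits to exercise the coverage
filter.  Every output is accompanied by its ground truth so downstream
stages are testable end to end.

The default composition encodes the family's published per-kingdom DA
frequencies: 70% (prokarya) / 80% (eukarya) bare catalytic domain, 15% with
one CBM, 12% / 3% with a C-terminal tail; the residual probability mass is
a rare catalytic+PKD architecture.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .architecture import (
    DEFAULT_CT_BINS, DomainHit, HIT_COLUMNS, KINGDOMS, KINGDOM_SUFFIX,
    CATALYTIC_LABEL, SequenceRecord,
)
from .phylo import AA_INDEX, AA_ORDER, Node, PhyloTree, write_newick

__all__ = [
    "FamilyProfile", "GroundTruth", "SimulatedFamily",
    "simulate_trait_phylogeny", "evolve_sequences", "simulate_family",
    "write_family",
]


class InfeasibleConfigurationError(ValueError):
    """The requested planted clades cannot be placed disjointly."""


#: Genera planted as thermostable+alkalophilic clades (Tr+Ak in the trait map).
TRAIT_CLADE_GENERA = [
    "Dictyoglomus", "Caldicellulosiruptor", "Thermobacillus",
    "Geobacillus", "Halorhabdus",
]
#: Background genus pools per kingdom (no Tr+Ak combination among them).
BACKGROUND_GENERA = {
    "prokarya": ["Streptomyces", "Paenibacillus", "Clostridium",
                 "Cellvibrio", "Jonesia", "Nesterenkonia"],
    "eukarya": ["Aspergillus", "Trichoderma", "Penicillium", "Fusarium"],
    "archaea": ["Thermococcus", "Pyrococcus", "Sulfolobus"],
}
#: Trait table emitted alongside the family (genus -> subset of Tr/Ak/Ac).
GENERATOR_TRAIT_TABLE: dict[str, frozenset[str]] = {
    "Dictyoglomus": frozenset({"Tr", "Ak"}),
    "Caldicellulosiruptor": frozenset({"Tr", "Ak"}),
    "Thermobacillus": frozenset({"Tr", "Ak"}),
    "Geobacillus": frozenset({"Tr", "Ak"}),
    "Halorhabdus": frozenset({"Tr", "Ak"}),
    "Bacillus": frozenset({"Tr", "Ak"}),
    "Thermopolyspora": frozenset({"Tr"}),
    "Thermobifida": frozenset({"Tr"}),
    "Aspergillus": frozenset({"Ac"}),
    "Penicillium": frozenset({"Ac"}),
    "Streptomyces": frozenset(),
    "Paenibacillus": frozenset(),
    "Clostridium": frozenset(),
    "Cellvibrio": frozenset(),
    "Jonesia": frozenset(),
    "Nesterenkonia": frozenset(),
    "Trichoderma": frozenset(),
    "Fusarium": frozenset(),
    "Thermococcus": frozenset(),
    "Pyrococcus": frozenset(),
    "Sulfolobus": frozenset(),
}

#: Accessory-domain model lengths (aa) used for hit emission.
ACCESSORY_MODEL_LEN = {
    "CBM6": 120, "CBM4_9": 140, "CBM60": 100, "CBM1": 36, "CBM10": 40,
    "PKD": 85,
}


@dataclass
class FamilyProfile:
    """Generator parameters; the defaults are the family's study conditions.

    Per-kingdom DA class probabilities must each lie in [0, 1] and sum to at
    most 1; the remainder is the rare catalytic+PKD class.
    """

    n_prokarya: int = 1000
    n_eukarya: int = 300
    n_archaea: int = 10
    frac_bare: dict[str, float] = field(default_factory=lambda: {
        "prokarya": 0.70, "eukarya": 0.80, "archaea": 0.70})
    frac_cbm: dict[str, float] = field(default_factory=lambda: {
        "prokarya": 0.15, "eukarya": 0.15, "archaea": 0.15})
    frac_ct: dict[str, float] = field(default_factory=lambda: {
        "prokarya": 0.12, "eukarya": 0.03, "archaea": 0.12})
    cbm_labels: dict[str, float] = field(default_factory=lambda: {
        "CBM6": 0.35, "CBM4_9": 0.25, "CBM60": 0.20, "CBM1": 0.15,
        "CBM10": 0.05})
    catalytic_model_length: int = 180
    mutation_rate: float = 1.0
    n_trait_clades: int = 3
    clade_size_range: tuple[int, int] = (3, 8)
    frac_partial: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_prokarya, self.n_eukarya, self.n_archaea):
            if n < 0:
                raise ValueError("sequence counts must be nonnegative")
        if self.catalytic_model_length <= 0:
            raise ValueError("catalytic_model_length must be positive")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be nonnegative")
        if not (0 <= self.frac_partial <= 1):
            raise ValueError("frac_partial must be in [0, 1]")
        for k in KINGDOMS:
            probs = (self.frac_bare[k], self.frac_cbm[k], self.frac_ct[k])
            if any(not (0 <= p <= 1) for p in probs):
                raise ValueError(f"{k}: DA probabilities must be in [0, 1]")
            if sum(probs) > 1 + 1e-9:
                raise ValueError(f"{k}: DA probabilities sum above 1")
        if abs(sum(self.cbm_labels.values()) - 1) > 1e-9:
            raise ValueError("cbm_labels probabilities must sum to 1")

    @property
    def n_total(self) -> int:
        return self.n_prokarya + self.n_eukarya + self.n_archaea


@dataclass
class GroundTruth:
    """Per-sequence truth emitted next to the synthetic family."""

    da: dict[str, str]                 # seq_id -> true DA string
    genus: dict[str, str]
    kingdom: dict[str, str]
    tree: PhyloTree
    trait_clades: list[frozenset[str]]  # planted Tr+Ak leaf sets
    partial_ids: frozenset[str]         # sequences given sub-threshold hits
    catalytic_span: dict[str, tuple[int, int]]


@dataclass
class SimulatedFamily:
    sequences: list[SequenceRecord]
    hits: list[DomainHit]
    taxonomy: dict[str, tuple[str, str]]  # seq_id -> (genus, kingdom)
    trait_table: dict[str, frozenset[str]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def _grow_tree(n_taxa: int, rng: np.random.Generator) -> PhyloTree:
    """Random bifurcating tree by repeated leaf splitting; branch lengths
    uniform on [0.05, 0.15]."""
    root = Node()
    leaves = [Node(), Node()]
    for leaf in leaves:
        root.add(leaf)
    while len(leaves) < n_taxa:
        i = int(rng.integers(len(leaves)))
        target = leaves[i]
        a, b = Node(), Node()
        target.add(a)
        target.add(b)
        leaves[i] = a
        leaves.append(b)
    tree = PhyloTree(root)
    width = len(str(n_taxa))
    counter = 0
    for node in tree.postorder():
        if node is not root:
            node.length = float(rng.uniform(0.05, 0.15))
        if node.is_leaf:
            counter += 1
            node.name = f"seq{counter:0{width}d}"
    return tree


def _plant_clades(
    tree: PhyloTree,
    n_clades: int,
    size_range: tuple[int, int],
    rng: np.random.Generator,
    max_ancestor_fraction: float = 0.5,
) -> list[Node]:
    """Choose disjoint internal nodes as trait clades.

    A candidate is accepted only if, with it planted, every ancestor keeps
    its planted-leaf fraction at or below ``max_ancestor_fraction`` — the
    planted clade is then the unique maximal trait-enriched clade around it,
    which is what "ground-truth clade" has to mean for exact recovery.
    """
    lo, hi = size_range
    sizes: dict[int, int] = {}
    internal: list[Node] = []
    for node in tree.postorder():
        if node.is_leaf:
            sizes[id(node)] = 1
        else:
            sizes[id(node)] = sum(sizes[id(c)] for c in node.children)
            if node is not tree.root and lo <= sizes[id(node)] <= hi:
                internal.append(node)
    order = rng.permutation(len(internal))
    planted_below: dict[int, int] = {}
    chosen: list[Node] = []

    def ancestors(node: Node):
        p = node.parent
        while p is not None:
            yield p
            p = p.parent

    for idx in order:
        if len(chosen) == n_clades:
            break
        cand = internal[idx]
        size = sizes[id(cand)]
        if planted_below.get(id(cand), 0) > 0:
            continue  # a chosen clade already sits at or below the candidate
        if any(a in chosen for a in ancestors(cand)):
            continue  # candidate sits inside a chosen clade
        ok = True
        for a in ancestors(cand):
            frac = (planted_below.get(id(a), 0) + size) / sizes[id(a)]
            if frac > max_ancestor_fraction:
                ok = False
                break
        if not ok:
            continue
        chosen.append(cand)
        for a in ancestors(cand):
            planted_below[id(a)] = planted_below.get(id(a), 0) + size
        planted_below[id(cand)] = size
    if len(chosen) < n_clades:
        raise InfeasibleConfigurationError(
            f"could only place {len(chosen)} of {n_clades} requested trait "
            f"clades of size {lo}-{hi} disjointly"
        )
    return chosen


def simulate_trait_phylogeny(
    n_taxa: int,
    n_trait_clades: int,
    seed: int,
    clade_size_range: tuple[int, int] = (2, 8),
) -> tuple[PhyloTree, dict[str, str], list[frozenset[str]]]:
    """Random bifurcating tree with trait-labelled clades planted on it.

    Returns ``(tree, genus-by-leaf, planted leaf sets)``.  Planted clades
    receive genera mapped to {Tr, Ak}; the rest of the leaves get background
    genera (traitless or acidophilic).
    """
    if n_taxa < 4:
        raise ValueError("n_taxa must be at least 4")
    if n_trait_clades < 0:
        raise ValueError("n_trait_clades must be nonnegative")
    rng = np.random.default_rng(seed)
    tree = _grow_tree(n_taxa, rng)
    clade_nodes = _plant_clades(tree, n_trait_clades, clade_size_range, rng)
    sets = tree.leafsets()
    clades = [sets[id(n)] for n in clade_nodes]

    genus: dict[str, str] = {}
    pool = list(rng.permutation(TRAIT_CLADE_GENERA))
    for i, clade in enumerate(clades):
        g = pool[i % len(pool)]
        for leaf in clade:
            genus[leaf] = g
    background = [g for pool_k in BACKGROUND_GENERA.values() for g in pool_k]
    for leaf in tree.leaf_names():
        if leaf not in genus:
            genus[leaf] = background[int(rng.integers(len(background)))]
    return tree, genus, clades


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def evolve_sequences(
    tree: PhyloTree,
    root_seq: str,
    rate: float,
    seed: int,
) -> dict[str, str]:
    """Evolve a sequence along the tree under a 20-state uniform-exchange
    (Jukes-Cantor-like) substitution model.

    Each site substitutes independently; the expected number of
    substitutions per site along a branch of length t is ``rate * t``
    (sampled exactly through the model's closed-form mismatch probability).
    """
    if not root_seq:
        raise ValueError("root sequence must be nonempty")
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    code = np.array([AA_INDEX[a] for a in root_seq], dtype=np.int64)
    out: dict[str, str] = {}

    # iterative traversal to avoid recursion limits on large trees
    stack: list[tuple[Node, np.ndarray]] = [(tree.root, code)]
    while stack:
        node, state = stack.pop()
        for child in node.children:
            t = child.length or 0.0
            p_diff = (19 / 20) * (1 - np.exp(-(20 / 19) * rate * t))
            mask = rng.random(state.size) < p_diff
            new = state.copy()
            if mask.any():
                shift = rng.integers(1, 20, size=int(mask.sum()))
                new[mask] = (new[mask] + shift) % 20
            if child.is_leaf:
                out[child.name] = "".join(AA_ORDER[i] for i in new)
            else:
                stack.append((child, new))
    return out


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=length))


def _accessory_block(label: str) -> str:
    """Fixed pseudo-random block per accessory-domain label; the per-label
    seed makes the block identical across runs and sequences."""
    length = ACCESSORY_MODEL_LEN[label]
    rng = np.random.default_rng(zlib.crc32(label.encode()))
    return _random_seq(length, rng)


# ---------------------------------------------------------------------------
# Family assembly
# ---------------------------------------------------------------------------

def simulate_family(profile: FamilyProfile) -> SimulatedFamily:
    """Generate sequences, domain hits, taxonomy and ground truth."""
    rng = np.random.default_rng(profile.seed)
    n = profile.n_total
    tree, genus, clades = simulate_trait_phylogeny(
        n, profile.n_trait_clades, int(rng.integers(2**31)),
        clade_size_range=profile.clade_size_range,
    )
    leaf_names = tree.leaf_names()

    # kingdoms: planted clades are prokaryotic; the rest fill the counts
    planted = {leaf for clade in clades for leaf in clade}
    if len(planted) > profile.n_prokarya:
        raise InfeasibleConfigurationError(
            "planted clades exceed the prokaryotic sequence count")
    kingdom: dict[str, str] = {leaf: "prokarya" for leaf in planted}
    rest = [l for l in leaf_names if l not in planted]
    rest = [rest[i] for i in rng.permutation(len(rest))]
    counts = [profile.n_prokarya - len(planted), profile.n_eukarya,
              profile.n_archaea]
    pos = 0
    for king, cnt in zip(KINGDOMS, counts):
        for leaf in rest[pos : pos + cnt]:
            kingdom[leaf] = king
        pos += cnt
    # background genera re-drawn per kingdom pool
    for leaf in rest:
        pool = BACKGROUND_GENERA[kingdom[leaf]]
        genus[leaf] = pool[int(rng.integers(len(pool)))]

    root_seq = _random_seq(profile.catalytic_model_length, rng)
    cat_seqs = evolve_sequences(tree, root_seq, profile.mutation_rate,
                                int(rng.integers(2**31)))

    cbm_names = list(profile.cbm_labels)
    cbm_probs = np.array([profile.cbm_labels[c] for c in cbm_names])
    L = profile.catalytic_model_length

    sequences: list[SequenceRecord] = []
    hits: list[DomainHit] = []
    truth_da: dict[str, str] = {}
    partial_ids: set[str] = set()
    catalytic_span: dict[str, tuple[int, int]] = {}

    for leaf in leaf_names:
        king = kingdom[leaf]
        p = [profile.frac_bare[king], profile.frac_cbm[king],
             profile.frac_ct[king]]
        p.append(max(0.0, 1.0 - sum(p)))
        cls = ["bare", "cbm", "ct", "other"][int(rng.choice(4, p=np.array(p) / sum(p)))]

        leader = int(rng.integers(0, 31))
        residues = _random_seq(leader, rng) + cat_seqs[leaf]
        cat_start, cat_end = leader + 1, leader + L
        catalytic_span[leaf] = (cat_start, cat_end)
        labels = [CATALYTIC_LABEL]
        ct_label = None
        seq_hits: list[tuple[str, int, int, int]] = []  # (label, start, end, model_len)

        if cls == "cbm":
            lbl = cbm_names[int(rng.choice(len(cbm_names), p=cbm_probs))]
            linker = int(rng.integers(5, 21))
            block = _accessory_block(lbl)
            start = len(residues) + linker + 1
            residues += _random_seq(linker, rng) + block
            seq_hits.append((lbl, start, start + len(block) - 1,
                             ACCESSORY_MODEL_LEN[lbl]))
            labels.append(lbl)
        elif cls == "other":
            linker = int(rng.integers(5, 21))
            block = _accessory_block("PKD")
            start = len(residues) + linker + 1
            residues += _random_seq(linker, rng) + block
            seq_hits.append(("PKD", start, start + len(block) - 1,
                             ACCESSORY_MODEL_LEN["PKD"]))
            labels.append("PKD")
        elif cls == "ct":
            tail_len = int(rng.integers(50, 501))
            residues += _random_seq(tail_len, rng)
            for label, lo, hi in DEFAULT_CT_BINS[:-1]:
                if lo <= tail_len < hi:
                    ct_label = label
                    break
            else:
                ct_label = DEFAULT_CT_BINS[-1][0]

        # catalytic hit: full model coverage, or a planted sub-threshold one
        if rng.random() < profile.frac_partial:
            partial_ids.add(leaf)
            cov = float(rng.uniform(0.50, 0.75))
            span = max(1, int(round(cov * L)))
            m_start = int(rng.integers(1, L - span + 2))
            m_end = m_start + span - 1
        else:
            m_start, m_end = 1, L
        hits.append(DomainHit(
            seq_id=leaf, domain_name=CATALYTIC_LABEL, model_length=L,
            seq_start=cat_start + m_start - 1, seq_end=cat_start + m_end - 1,
            model_start=m_start, model_end=m_end,
            score=round(2.0 * (m_end - m_start + 1), 1), evalue=1e-50,
        ))
        for lbl, s, e, mlen in seq_hits:
            hits.append(DomainHit(
                seq_id=leaf, domain_name=lbl, model_length=mlen,
                seq_start=s, seq_end=e, model_start=1, model_end=mlen,
                score=round(1.5 * mlen, 1), evalue=1e-30,
            ))

        da = "+".join(labels + ([ct_label] if ct_label else []))
        truth_da[leaf] = da + KINGDOM_SUFFIX[king]
        sequences.append(SequenceRecord(leaf, f"synthetic {king}", residues))

    taxonomy = {leaf: (genus[leaf], kingdom[leaf]) for leaf in leaf_names}
    truth = GroundTruth(
        da=truth_da, genus=genus, kingdom=kingdom, tree=tree,
        trait_clades=clades, partial_ids=frozenset(partial_ids),
        catalytic_span=catalytic_span,
    )
    return SimulatedFamily(sequences, hits, taxonomy,
                           dict(GENERATOR_TRAIT_TABLE), truth)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_family(fam: SimulatedFamily, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, hit table, taxonomy, trait table, true tree and truth
    table into ``out_dir``; returns the path of each artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "family.fasta",
        "hits": out / "hits.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "traits": out / "traits.tsv",
        "tree": out / "true_tree.nwk",
        "truth": out / "truth.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for rec in fam.sequences:
            fh.write(f">{rec.id} {rec.description}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")
    with open(paths["hits"], "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in fam.hits:
            fh.write("\t".join(str(x) for x in (
                h.seq_id, h.domain_name, h.model_length,
                h.seq_start, h.seq_end, h.model_start, h.model_end,
                h.score, h.evalue)) + "\n")
    with open(paths["taxonomy"], "w") as fh:
        fh.write("seq_id\tgenus\tkingdom\n")
        for sid, (g, k) in fam.taxonomy.items():
            fh.write(f"{sid}\t{g}\t{k}\n")
    with open(paths["traits"], "w") as fh:
        fh.write("genus\ttraits\n")
        for g in sorted(fam.trait_table):
            fh.write(f"{g}\t{','.join(sorted(fam.trait_table[g]))}\n")
    paths["tree"].write_text(write_newick(fam.truth.tree) + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("seq_id\tda\tgenus\tkingdom\tpartial_hit\tclade\n")
        clade_of = {}
        for i, clade in enumerate(fam.truth.trait_clades, start=1):
            for leaf in clade:
                clade_of[leaf] = i
        for rec in fam.sequences:
            sid = rec.id
            fh.write("\t".join(str(x) for x in (
                sid, fam.truth.da[sid], fam.truth.genus[sid],
                fam.truth.kingdom[sid],
                int(sid in fam.truth.partial_ids),
                clade_of.get(sid, 0))) + "\n")
    return paths
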