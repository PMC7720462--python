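"""End-to-end pipeline: simulate -> classify -> extract -> tree -> screen,
plus the saccharification-yield arithmetic used to judge enzyme performance.

All randomness flows from one top-level seed, so a fixed configuration
reproduces its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import architecture as arch
from . import catalytic, phylo, screen, synthetic

logger = logging.getLogger("xynscreen.pipeline")

#: Xylose (150.13 Da) minus water: the per-residue mass inside the xylan chain.
ANHYDROXYLOSE_MASS = 132.11


# ---------------------------------------------------------------------------
# Saccharification-yield arithmetic
# ---------------------------------------------------------------------------

@dataclass
class YieldParams:
    """Substrate parameters for the theoretical reducing-sugar maximum.

    ``loading``: substrate in g/L (10% w/v = 100 g/L).
    ``hemicellulose_fraction``: hemicellulose mass fraction of the substrate
    (rice straw: 0.18-0.25).
    ``anhydro_monomer_mass``: g/mol of one sugar residue inside the polymer.
    """

    loading: float = 100.0
    hemicellulose_fraction: float = 0.20
    anhydro_monomer_mass: float = ANHYDROXYLOSE_MASS

    def __post_init__(self) -> None:
        if self.loading < 0:
            raise ValueError("loading must be nonnegative")
        if not (0 <= self.hemicellulose_fraction <= 1):
            raise ValueError("hemicellulose_fraction must be in [0, 1]")
        if self.anhydro_monomer_mass <= 0:
            raise ValueError("anhydro_monomer_mass must be positive")


def theoretical_reducing_sugar_mM(p: YieldParams) -> float:
    """Maximal reducing sugars (mM of monosaccharide equivalents) if the
    hemicellulose fraction were fully depolymerised:
    1000 * loading * fraction / monomer_mass."""
    return 1000.0 * p.loading * p.hemicellulose_fraction / p.anhydro_monomer_mass


def percent_of_theoretical(measured_mM: float, theoretical_mM: float) -> float:
    """Measured yield as a percentage of the theoretical maximum."""
    if theoretical_mM <= 0:
        raise ValueError("theoretical maximum must be positive")
    return 100.0 * measured_mM / theoretical_mM


def specific_activity(reducing_sugar_umol: float, time_min: float,
                      protein_mg: float) -> float:
    """Units per mg: 1 U = 1 umol reducing sugars released per min per mg."""
    if time_min <= 0 or protein_mg <= 0:
        raise ValueError("time and protein amount must be positive")
    return reducing_sugar_umol / (time_min * protein_mg)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ScreenConfig:
    """Everything one pipeline run needs; round-trips through YAML.

    The default profile is a scaled-down family (50 sequences, 100 bootstrap
    replicates) sized so the alignment/bootstrap stages finish in seconds;
    the composition probabilities are the family defaults.
    """

    seed: int = 0
    # family generation (None -> profile defaults)
    n_prokarya: int = 40
    n_eukarya: int = 10
    n_archaea: int = 0
    n_trait_clades: int = 2
    frac_partial: float = 0.10
    # classification
    coverage_threshold: float = 0.80
    # phylogeny
    kmer_size: int = 3
    gap_penalty: float = phylo.DEFAULT_GAP_PENALTY
    n_bootstrap: int = 100
    # screening
    target_traits: tuple[str, ...] = ("Tr", "Ak")
    support_min: int = 50
    purity_min: float = 0.6
    min_cluster_size: int = 3
    n_representatives: int = 7

    def __post_init__(self) -> None:
        if not (0 < self.coverage_threshold <= 1):
            raise ValueError("coverage_threshold must be in (0, 1]")
        if not (0 <= self.purity_min <= 1):
            raise ValueError("purity_min must be in [0, 1]")
        if not (0 <= self.support_min <= 100):
            raise ValueError("support_min must be in [0, 100]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        bad = set(self.target_traits) - set(screen.TRAITS)
        if bad:
            raise ValueError(f"unknown target traits: {sorted(bad)}")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["target_traits"] = list(self.target_traits)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "target_traits" in data:
            data["target_traits"] = tuple(data["target_traits"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: ScreenConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run simulate -> classify -> extract -> tree -> screen.

    Writes all intermediate artifacts under ``out_dir`` and returns their
    paths.  Identical config (including seed) gives byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        profile = synthetic.FamilyProfile(
            n_prokarya=config.n_prokarya,
            n_eukarya=config.n_eukarya,
            n_archaea=config.n_archaea,
            n_trait_clades=config.n_trait_clades,
            frac_partial=config.frac_partial,
            seed=config.seed,
        )
        fam = synthetic.simulate_family(profile)
        paths.update(synthetic.write_family(fam, out / "family"))
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    try:
        stage("classify")
        das, discarded = arch.classify_all(
            fam.sequences, fam.hits, fam.taxonomy,
            threshold=config.coverage_threshold,
        )
        tab = arch.tabulate_architectures(das)
        paths["da_table"] = out / "da_table.tsv"
        tab.to_csv(paths["da_table"], sep="\t", index=False,
                   float_format="%.4f")
        paths["da_assignments"] = out / "da_assignments.tsv"
        with open(paths["da_assignments"], "w") as fh:
            fh.write("seq_id\tda_string\tkingdom\n")
            for d in sorted(das, key=lambda d: d.seq_id):
                fh.write(f"{d.seq_id}\t{d.da_string}\t{d.kingdom}\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc

    try:
        stage("extract")
        retained = {d.seq_id for d in das}
        seq_by_id = {s.id: s for s in fam.sequences}
        domains = []
        for h in fam.hits:
            if (h.domain_name == arch.CATALYTIC_LABEL
                    and h.seq_id in retained
                    and arch.coverage(h) >= config.coverage_threshold):
                domains.append(catalytic.extract_catalytic_domain(
                    seq_by_id[h.seq_id], h))
        paths["domains"] = out / "domains.fasta"
        catalytic.write_domains_fasta(domains, paths["domains"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("extract", exc) from exc

    try:
        stage("tree")
        seqs = [(d.parent_id, d.residues) for d in domains]
        aln = phylo.progressive_msa(seqs, gap=config.gap_penalty,
                                    k=config.kmer_size)
        paths["alignment"] = out / "alignment.fasta"
        with open(paths["alignment"], "w") as fh:
            for sid, row in zip(aln.ids, aln.rows):
                fh.write(f">{sid}\n{row}\n")
        tree = phylo.bootstrap_supports(
            aln, n_reps=config.n_bootstrap, seed=config.seed)
        paths["tree"] = out / "tree.nwk"
        paths["tree"].write_text(phylo.write_newick(tree) + "\n")
    except Exception as exc:  # noqa: BLE001
        raise StageError("tree", exc) from exc

    try:
        stage("screen")
        leaf_traits = screen.annotate_traits(tree, fam.taxonomy,
                                             fam.trait_table)
        da_of = {d.seq_id: d.da_string for d in das}
        target = frozenset(config.target_traits)
        clusters = screen.find_candidate_clusters(
            tree, leaf_traits, target=target,
            support_min=config.support_min,
            purity_min=config.purity_min,
            min_cluster_size=config.min_cluster_size,
            das=da_of,
        )
        for c in clusters:
            c.representatives = screen.select_representatives(
                c, da_of, config.n_representatives, tree=tree)
        paths["clusters"] = out / "clusters.tsv"
        screen.write_cluster_report(clusters, paths["clusters"], target)
    except Exception as exc:  # noqa: BLE001
        raise StageError("screen", exc) from exc

    paths["config"] = out / "config.yaml"
    config.to_yaml(paths["config"])
    paths["run_log"] = out / "run.txt"
    paths["run_log"].write_text(
        f"seed\t{config.seed}\n"
        f"sequences\t{len(fam.sequences)}\n"
        f"discarded_by_coverage\t{len(discarded)}\n"
        f"classified\t{len(das)}\n"
        f"clusters\t{len(clusters)}\n"
    )
    return paths
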