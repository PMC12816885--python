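"""Synthetic inputs with planted genus structure and known truth.

The generator emulates the statistical structure that genome-based
genus demarcation exploits: a species tree with a balanced genus
backbone, proteomes whose pairwise amino-acid identity decays with
patristic distance (so the pooled AAI distribution is bimodal with a
valley between the within- and between-genus modes), branch-wise gene
loss (so POCP varies below 100), and a marker gene carried by a
phylogenetically coherent subset of genomes with a matched phenotype.

Substitutions follow a 20-state Jukes-Cantor-type model (Poisson
events, uniform replacement), giving the closed-form expected identity

    E[identity] = floor + (100 - floor) * exp(-d * 20 / 19)

for total path distance d (substitutions/site), with floor = 5 % being
the random-alignment baseline.  The closed form is recorded per pair in
the truth table, making parameter-recovery tests exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .homology import Proteome
from .io import SequenceRecord, write_fasta, write_newick
from .marker import GeneTree

__all__ = [
    "SimConfig",
    "TruthTable",
    "MarkerSim",
    "SimulationResult",
    "expected_identity",
    "depth_for_identity",
    "simulate_tree",
    "simulate_proteomes",
    "simulate_marker",
    "simulate_all",
    "write_run_dir",
]

AA_LETTERS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def expected_identity(distance: float, floor: float = 5.0) -> float:
    """Expected percent identity after total path *distance* subs/site."""
    return floor + (100.0 - floor) * math.exp(-distance * 20.0 / 19.0)


def depth_for_identity(identity: float, floor: float = 5.0) -> float:
    """Total path distance (subs/site) at which expected identity equals
    *identity*; inverse of :func:`expected_identity`."""
    if not floor < identity <= 100.0:
        raise ValueError("identity must lie in (floor, 100]")
    return -19.0 / 20.0 * math.log((identity - floor) / (100.0 - floor))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic run.

    Default depths plant within-genus pairs at ~85 % expected identity
    and between-genus pairs at ~70 %, so the pooled AAI distribution has
    a valley inside the 60-80 % search window.
    """

    n_genera: int = 2
    genomes_per_genus: int = 5
    intra_depth: float = depth_for_identity(85.0)   # ~0.164 subs/site
    inter_depth: float = depth_for_identity(70.0)   # ~0.360 subs/site
    n_families: int = 150
    family_length: int = 100
    loss_prob_per_branch: float = 0.03
    identity_floor: float = 5.0
    marker_genera: tuple[str, ...] = ("G1",)
    n_reference_genes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_genera < 2:
            problems.append("n_genera must be >= 2")
        if self.genomes_per_genus < 2:
            problems.append("genomes_per_genus must be >= 2")
        if not self.inter_depth > self.intra_depth:
            problems.append("inter_depth must exceed intra_depth")
        if self.intra_depth < 0:
            problems.append("intra_depth must be >= 0")
        if not 0 <= self.loss_prob_per_branch < 1:
            problems.append("loss_prob_per_branch must be in [0, 1)")
        if not 0 <= self.identity_floor < 100:
            problems.append("identity_floor must be in [0, 100)")
        if self.n_families < 1 or self.family_length < 1:
            problems.append("n_families and family_length must be >= 1")
        unknown = set(self.marker_genera) - set(self.genus_labels())
        if unknown:
            problems.append(f"marker_genera not among genus labels: {sorted(unknown)}")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))

    def genus_labels(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genera)]

    def genome_ids(self) -> list[str]:
        return [f"{g}_g{k + 1:02d}" for g in self.genus_labels()
                for k in range(self.genomes_per_genus)]


@dataclass
class TruthTable:
    """Planted ground truth for parameter-recovery tests."""

    genus_of: dict[str, str]
    expected_identity: dict[tuple[str, str], float] = field(default_factory=dict)
    marker_presence: dict[str, bool] = field(default_factory=dict)
    phenotype: dict[str, str] = field(default_factory=dict)

    def genera(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for genome, genus in self.genus_of.items():
            out.setdefault(genus, set()).add(genome)
        return out

    def to_json(self) -> str:
        payload = {
            "genus_of": self.genus_of,
            "expected_identity": {f"{a}|{b}": v
                                  for (a, b), v in sorted(self.expected_identity.items())},
            "marker_presence": self.marker_presence,
            "phenotype": self.phenotype,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class MarkerSim:
    gene_records: list[SequenceRecord]
    gene_tree: GeneTree
    phenotype: dict[str, str]


@dataclass
class SimulationResult:
    config: SimConfig
    tree: dendropy.Tree
    proteomes: list[Proteome]
    truth: TruthTable
    marker: MarkerSim


def _ultrametric_subtree(leaf_names: Sequence[str], depth: float,
                         rng: np.random.Generator,
                         taxa: dendropy.TaxonNamespace) -> dendropy.Node:
    """Random coalescent-style ultrametric topology of total height *depth*.

    Coalescences are drawn from the deepest fifth of the clade (heights
    in [0.8, 1.0] x depth), so every within-genus pairwise distance stays
    close to 2 x depth and the planted within-genus identity concentrates
    at the value implied by the configured intra depth instead of
    spreading far above it.
    """
    lineages: list[tuple[dendropy.Node, float]] = []
    for name in leaf_names:
        node = dendropy.Node()
        node.taxon = taxa.require_taxon(label=name)
        lineages.append((node, 0.0))
    n_merges = len(leaf_names) - 1
    if n_merges == 0:
        node, _ = lineages[0]
        node.edge.length = depth
        return node
    times = np.sort(rng.uniform(0.8 * depth, depth, size=n_merges - 1)).tolist() + [depth]
    for t in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, ha), (b, hb) = lineages[i], lineages[j]
        parent = dendropy.Node()
        a.edge.length = t - ha
        b.edge.length = t - hb
        parent.add_child(a)
        parent.add_child(b)
        lineages = [lineages[k] for k in range(len(lineages)) if k not in (i, j)]
        lineages.append((parent, t))
    root, _ = lineages[0]
    return root


def simulate_tree(cfg: SimConfig) -> tuple[dendropy.Tree, TruthTable]:
    """Balanced genus backbone with random within-genus branching.

    Genus subtrees are ultrametric at height ``intra_depth / 2`` (so
    within-genus pairwise distance <= intra_depth) on stems of length
    ``(inter_depth - intra_depth) / 2`` (so between-genus distance is
    exactly inter_depth).  Deterministic under the config seed.
    """
    rng = np.random.default_rng([0, cfg.seed])
    taxa = dendropy.TaxonNamespace()
    root = dendropy.Node()
    stem = (cfg.inter_depth - cfg.intra_depth) / 2.0
    genus_of: dict[str, str] = {}
    for genus in cfg.genus_labels():
        names = [f"{genus}_g{k + 1:02d}" for k in range(cfg.genomes_per_genus)]
        for n in names:
            genus_of[n] = genus
        sub = _ultrametric_subtree(names, cfg.intra_depth / 2.0, rng, taxa)
        sub.edge.length = (sub.edge.length or 0.0) + stem
        root.add_child(sub)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    root.edge.length = 0.0
    truth = TruthTable(genus_of=genus_of)
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(genus_of)
    tax = {t.label: t for t in taxa}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = pdm.patristic_distance(tax[a], tax[b])
            truth.expected_identity[(a, b)] = expected_identity(d, cfg.identity_floor)
    return tree, truth


def _evolve_along(tree: dendropy.Tree, root_seq: np.ndarray,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve an integer-coded sequence down the tree (JC-20 model);
    returns leaf label -> sequence array."""
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            parent_seq = seqs[id(node.parent_node)]
            d = node.edge.length or 0.0
            p_change = (19.0 / 20.0) * (1.0 - math.exp(-d * 20.0 / 19.0))
            mask = rng.random(parent_seq.size) < p_change
            seq = parent_seq.copy()
            if mask.any():
                # uniform over the 19 other states
                shift = rng.integers(1, 20, size=int(mask.sum()))
                seq[mask] = (seq[mask] + shift) % 20
            seqs[id(node)] = seq
        if node.is_leaf():
            out[node.taxon.label] = seqs[id(node)]
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(AA_LETTERS[seq])


def simulate_proteomes(tree: dendropy.Tree, cfg: SimConfig
                       ) -> tuple[list[Proteome], TruthTable]:
    """Evolve ``n_families`` protein families along the tree with
    branch-wise irreversible loss; returns proteomes plus the truth table
    (genus labels and closed-form expected pairwise identities)."""
    rng = np.random.default_rng([1, cfg.seed])
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    proteins: dict[str, list[SequenceRecord]] = {g: [] for g in leaf_labels}
    for fam in range(cfg.n_families):
        root_seq = rng.integers(0, 20, size=cfg.family_length)
        leaf_seqs = _evolve_along(tree, root_seq, rng)
        # branch-wise irreversible loss
        present: dict[int, bool] = {id(tree.seed_node): True}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            p = present[id(node.parent_node)]
            present[id(node)] = bool(p and rng.random() >= cfg.loss_prob_per_branch)
        for lf in tree.leaf_node_iter():
            if present[id(lf)]:
                label = lf.taxon.label
                proteins[label].append(SequenceRecord(
                    id=f"{label}|fam{fam:03d}", description="",
                    seq=_decode(leaf_seqs[label])))
    proteomes = [Proteome(genome_id=g, proteins=proteins[g]) for g in sorted(proteins)]
    return proteomes, _truth_for(tree, cfg)


def _truth_for(tree: dendropy.Tree, cfg: SimConfig) -> TruthTable:
    genus_of = {}
    for lf in tree.leaf_node_iter():
        label = lf.taxon.label
        genus_of[label] = label.split("_")[0] if "_" in label else label
    truth = TruthTable(genus_of=genus_of)
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace if t.label in genus_of}
    labels = sorted(genus_of)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = pdm.patristic_distance(tax[a], tax[b])
            truth.expected_identity[(a, b)] = expected_identity(d, cfg.identity_floor)
    return truth


def simulate_marker(tree: dendropy.Tree, cfg: SimConfig) -> MarkerSim:
    """Marker gene carried only by the genomes of ``marker_genera``.

    The gene tree is the induced subtree of carrier genomes with
    ``n_reference_genes`` experimentally validated reference sequences
    grafted inside the carrier clade (across the children of its root,
    so the validated clade spans exactly the carriers).  Phenotype is
    carrier status.
    """
    rng = np.random.default_rng([2, cfg.seed])
    carriers = [lf.taxon.label for lf in tree.leaf_node_iter()
                if lf.taxon.label.split("_")[0] in cfg.marker_genera]
    if len(carriers) < 2:
        raise ValueError("need at least 2 carrier genomes")
    gtree = tree.extract_tree_with_taxa_labels(carriers)
    gtree.is_rooted = True
    # locate the carrier MRCA in the extracted tree
    carrier_mrca = gtree.mrca(taxa=[t for t in gtree.taxon_namespace
                                    if t.label in carriers])
    children = carrier_mrca.child_nodes()
    for k in range(cfg.n_reference_genes):
        child = children[k % len(children)]
        length = child.edge.length or 0.0
        mid = dendropy.Node()
        parent = child.parent_node
        parent.remove_child(child)
        parent.add_child(mid)
        mid.edge.length = length / 2.0
        mid.add_child(child)
        child.edge.length = length / 2.0
        ref = dendropy.Node()
        ref.taxon = gtree.taxon_namespace.require_taxon(label=f"REF{k + 1}")
        mid.add_child(ref)
        ref.edge.length = max(length / 2.0, 1e-3)
        children = carrier_mrca.child_nodes()  # refresh (mid replaced child)
    # relabel carrier leaves as gene ids and evolve sequences
    gene_to_genome: dict[str, str] = {}
    for lf in gtree.leaf_node_iter():
        lab = lf.taxon.label
        if lab.startswith("REF"):
            continue
        gene_id = f"tnaA|{lab}"
        lf.taxon = gtree.taxon_namespace.require_taxon(label=gene_id)
        gene_to_genome[gene_id] = lab
    gtree.update_taxon_namespace()
    root_seq = rng.integers(0, 20, size=cfg.family_length)
    leaf_seqs = _evolve_along(gtree, root_seq, rng)
    records = [SequenceRecord(id=lab, description="", seq=_decode(s))
               for lab, s in sorted(leaf_seqs.items())]
    reference_ids = frozenset(f"REF{k + 1}" for k in range(cfg.n_reference_genes))
    phenotype = {lf.taxon.label: ("positive" if lf.taxon.label in carriers else "negative")
                 for lf in tree.leaf_node_iter()}
    gene_tree = GeneTree(tree=gtree, gene_to_genome=gene_to_genome,
                         reference_ids=reference_ids)
    return MarkerSim(gene_records=records, gene_tree=gene_tree, phenotype=phenotype)


def simulate_all(cfg: SimConfig) -> SimulationResult:
    """Full synthetic dataset: tree, proteomes, marker and truth."""
    tree, truth = simulate_tree(cfg)
    proteomes, _ = simulate_proteomes(tree, cfg)
    marker = simulate_marker(tree, cfg)
    truth.marker_presence = {g: (truth.genus_of[g] in cfg.marker_genera)
                             for g in truth.genus_of}
    truth.phenotype = dict(marker.phenotype)
    return SimulationResult(config=cfg, tree=tree, proteomes=proteomes,
                            truth=truth, marker=marker)


def write_run_dir(result: SimulationResult, outdir: str | Path) -> Path:
    """Persist a simulation as the pipeline's on-disk input layout."""
    out = Path(outdir) / f"sim_seed{result.config.seed}"
    (out / "proteomes").mkdir(parents=True, exist_ok=True)
    for p in result.proteomes:
        write_fasta(p.proteins, out / "proteomes" / f"{p.genome_id}.faa")
    (out / "tree.nwk").write_text(write_newick(result.tree) + "\n")
    write_fasta(result.marker.gene_records, out / "marker.faa")
    (out / "gene_tree.nwk").write_text(write_newick(result.marker.gene_tree.tree) + "\n")
    with open(out / "gene_to_genome.tsv", "w") as fh:
        fh.write("gene_id\tgenome_id\n")
        for gene, genome in sorted(result.marker.gene_tree.gene_to_genome.items()):
            fh.write(f"{gene}\t{genome}\n")
    with open(out / "reference_ids.txt", "w") as fh:
        for rid in sorted(result.marker.gene_tree.reference_ids):
            fh.write(rid + "\n")
    with open(out / "phenotype.tsv", "w") as fh:
        fh.write("genome_id\tphenotype\n")
        for genome, ph in sorted(result.marker.phenotype.items()):
            fh.write(f"{genome}\t{ph}\n")
    (out / "truth.json").write_text(result.truth.to_json() + "\n")
    return out
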