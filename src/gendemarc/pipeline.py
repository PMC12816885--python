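"""End-to-end orchestration: metrics -> boundary -> delineation -> RED ->
marker concordance, with persisted intermediates and a machine-readable
report.

Every stage either contributes results to the report or records an
explicit skip reason; a stage failure aborts with the stage name while
retaining partial outputs.  Reports are deterministic for identical
inputs and configuration (no timestamps in the report itself).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .boundary import DEFAULT_ADJUSTS, ThresholdEstimate, bandwidth_sweep
from .delineate import GenusPartition, build_graph, delineate
from .homology import AlignParams, PairMetrics, Proteome, pair_metrics
from .io import SequenceRecord, global_identity, read_fasta, read_newick
from .marker import GeneTree, concordance, genome_membership, validated_clade
from .red import compute_red, core_clade_red, taxon_red

logger = logging.getLogger("gendemarc")

__all__ = [
    "RunConfig",
    "RunReport",
    "StageError",
    "run",
    "compute_all_pair_metrics",
    "metrics_to_frame",
    "frame_to_metrics",
    "validate_16s",
    "GENUS_16S_BAND",
]

# commonly accepted genus-level band for 16S similarity (percent)
GENUS_16S_BAND = (92.0, 95.0)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    proteome_dir: str | Path
    tree_path: str | Path
    output_dir: str | Path
    gene_tree_path: Optional[str | Path] = None
    gene_to_genome_path: Optional[str | Path] = None
    reference_ids_path: Optional[str | Path] = None
    phenotype_path: Optional[str | Path] = None
    taxon_map_path: Optional[str | Path] = None
    pocp_threshold: float = 50.0
    aai_threshold: float | str = "auto"  # "auto" = KDE local minimum at adjust 1
    sweep_lo: float = 60.0
    sweep_hi: float = 80.0
    sweep_adjusts: tuple[float, ...] = DEFAULT_ADJUSTS
    align_params: AlignParams = field(default_factory=AlignParams)
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class RunReport:
    config_echo: dict
    provenance: dict
    pair_metrics: list[PairMetrics]
    threshold: Optional[ThresholdEstimate]
    aai_threshold_used: Optional[float]
    partition: Optional[GenusPartition]
    red_groups: dict[str, float]
    concordance: Optional[dict]
    skipped: dict[str, str]

    def to_json(self) -> str:
        payload = {
            "version": 1,
            "provenance": self.provenance,
            "config": self.config_echo,
            "n_pairs": len(self.pair_metrics),
            "threshold": None if self.threshold is None else {
                "minimum_at": self.threshold.minimum_at,
                "sweep_interval": self.threshold.sweep_interval,
                "n_modes_in_range": self.threshold.n_modes_in_range,
                "search_range": [self.threshold.search_lo, self.threshold.search_hi],
            },
            "aai_threshold_used": self.aai_threshold_used,
            "groups": None if self.partition is None else [
                sorted(g) for g in self.partition.groups],
            "excluded": None if self.partition is None else self.partition.excluded,
            "red_groups": self.red_groups,
            "concordance": self.concordance,
            "skipped": self.skipped,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def compute_all_pair_metrics(proteomes: Sequence[Proteome],
                             params: AlignParams | None = None) -> list[PairMetrics]:
    """Metrics for every unordered pair, ordered by (genome_a, genome_b)."""
    params = params or AlignParams()
    ordered = sorted(proteomes, key=lambda p: p.genome_id)
    out = []
    for a, b in combinations(ordered, 2):
        logger.debug("pair metrics: %s vs %s", a.genome_id, b.genome_id)
        out.append(pair_metrics(a, b, params))
    return out


def metrics_to_frame(metrics: Sequence[PairMetrics]) -> pd.DataFrame:
    return pd.DataFrame([{
        "genome_a": m.genome_a, "genome_b": m.genome_b,
        "aai": m.aai, "n_rbh": m.n_rbh, "pocp": m.pocp,
        "c_a": m.c_a, "c_b": m.c_b, "t_a": m.t_a, "t_b": m.t_b,
    } for m in metrics])


def frame_to_metrics(df: pd.DataFrame) -> list[PairMetrics]:
    out = []
    for row in df.itertuples(index=False):
        aai_val = None if pd.isna(row.aai) else float(row.aai)
        out.append(PairMetrics(
            genome_a=str(row.genome_a), genome_b=str(row.genome_b),
            aai=aai_val, n_rbh=int(row.n_rbh), pocp=float(row.pocp),
            c_a=int(row.c_a), c_b=int(row.c_b), t_a=int(row.t_a), t_b=int(row.t_b)))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_proteomes(directory: Path) -> list[Proteome]:
    files = sorted(p for p in directory.iterdir()
                   if p.suffix in (".faa", ".fasta", ".fa"))
    if not files:
        raise FileNotFoundError(f"no proteome FASTA files in {directory}")
    return [Proteome(genome_id=f.stem, proteins=read_fasta(f, "aa")) for f in files]


def _load_gene_tree(cfg: RunConfig) -> GeneTree:
    tree = read_newick(Path(cfg.gene_tree_path))
    g2g = {}
    df = pd.read_csv(cfg.gene_to_genome_path, sep="\t")
    for row in df.itertuples(index=False):
        g2g[str(row.gene_id)] = str(row.genome_id)
    refs = frozenset(l.strip() for l in Path(cfg.reference_ids_path).read_text().split()
                     if l.strip())
    return GeneTree(tree=tree, gene_to_genome=g2g, reference_ids=refs)


def _load_phenotype(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.genome_id): str(r.phenotype) for r in df.itertuples(index=False)}


def run(cfg: RunConfig) -> RunReport:
    """Execute all stages in order; see module docstring."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    skipped: dict[str, str] = {}

    # stage: inputs
    try:
        proteomes = _load_proteomes(Path(cfg.proteome_dir))
        tree = read_newick(Path(cfg.tree_path))
    except Exception as exc:
        raise StageError("load_inputs", exc) from exc
    provenance = {
        "package_version": __version__,
        "seed": cfg.seed,
        "n_genomes": len(proteomes),
        "tree_digest": _sha256(Path(cfg.tree_path)),
    }

    # stage: pairwise metrics
    try:
        metrics = compute_all_pair_metrics(proteomes, cfg.align_params)
        metrics_to_frame(metrics).to_csv(outdir / "pair_metrics.tsv",
                                         sep="\t", index=False)
    except Exception as exc:
        raise StageError("metrics", exc) from exc

    # stage: boundary detection
    threshold: Optional[ThresholdEstimate] = None
    aai_values = [m.aai for m in metrics if m.aai is not None]
    if cfg.aai_threshold == "auto":
        if len(aai_values) < 10:
            raise StageError("boundary", ValueError(
                "auto threshold needs >= 10 defined pairwise AAI values, "
                f"got {len(aai_values)}"))
        try:
            threshold = bandwidth_sweep(aai_values, cfg.sweep_adjusts,
                                        cfg.sweep_lo, cfg.sweep_hi)
        except Exception as exc:
            raise StageError("boundary", exc) from exc
        if threshold.minimum_at is None:
            raise StageError("boundary", ValueError(
                "no AAI valley found in the search range; supply a fixed "
                "aai_threshold"))
        aai_used = threshold.minimum_at
    else:
        aai_used = float(cfg.aai_threshold)
        if len(aai_values) >= 10:
            try:
                threshold = bandwidth_sweep(aai_values, cfg.sweep_adjusts,
                                            cfg.sweep_lo, cfg.sweep_hi)
            except ValueError:
                threshold = None

    # stage: delineation
    try:
        graph = build_graph(metrics, aai_threshold=aai_used,
                            pocp_threshold=cfg.pocp_threshold)
        partition = delineate(tree, graph)
        rows = []
        for i, g in enumerate(partition.groups):
            for genome in sorted(g):
                rows.append({"genome_id": genome, "group_id": f"group{i + 1}",
                             "status": "grouped", "reason": ""})
        for genome, reason in sorted(partition.excluded.items()):
            rows.append({"genome_id": genome, "group_id": "",
                         "status": "excluded", "reason": reason})
        pd.DataFrame(rows).to_csv(outdir / "partition.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("delineation", exc) from exc

    # stage: RED
    red_groups: dict[str, float] = {}
    try:
        redmap = compute_red(tree)
        for i, g in enumerate(partition.groups):
            if g:
                red_groups[f"group{i + 1}"] = taxon_red(redmap, g).value
    except Exception as exc:
        raise StageError("red", exc) from exc

    # stage: marker concordance (optional inputs)
    conc = None
    marker_inputs = (cfg.gene_tree_path, cfg.gene_to_genome_path,
                     cfg.reference_ids_path, cfg.phenotype_path)
    if all(p is not None for p in marker_inputs):
        try:
            gtree = _load_gene_tree(cfg)
            clade = validated_clade(gtree)
            membership = genome_membership(gtree, clade)
            phenotype = _load_phenotype(Path(cfg.phenotype_path))
            table = concordance(membership, phenotype)
            conc = {
                "n11": table.n11, "n10": table.n10,
                "n01": table.n01, "n00": table.n00,
                "n_absent_negative": table.n_absent_negative,
                "n_absent_positive": table.n_absent_positive,
                "agreement": table.agreement if table.total else None,
            }
        except Exception as exc:
            raise StageError("marker", exc) from exc
    else:
        skipped["marker"] = "marker inputs not provided"

    report = RunReport(
        config_echo={
            "pocp_threshold": cfg.pocp_threshold,
            "aai_threshold": cfg.aai_threshold,
            "sweep": [cfg.sweep_lo, cfg.sweep_hi, list(cfg.sweep_adjusts)],
            "seed": cfg.seed,
        },
        provenance=provenance,
        pair_metrics=metrics,
        threshold=threshold,
        aai_threshold_used=aai_used,
        partition=partition,
        red_groups=red_groups,
        concordance=conc,
        skipped=skipped,
    )
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report


def validate_16s(query: SequenceRecord,
                 references: Sequence[SequenceRecord]) -> pd.DataFrame:
    """Rank references by global 16S identity against the query.

    Rows below the commonly accepted genus-level similarity band
    (92-95 %) are flagged ``sub_genus``.
    """
    if not references:
        raise ValueError("empty reference set")
    rows = []
    for ref in references:
        ident = global_identity(query, ref)
        rows.append({
            "reference_id": ref.id,
            "identity": ident,
            "flag": "sub_genus" if ident < GENUS_16S_BAND[0] else "",
        })
    df = pd.DataFrame(rows).sort_values(
        ["identity", "reference_id"], ascending=[False, True], ignore_index=True)
    return df
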