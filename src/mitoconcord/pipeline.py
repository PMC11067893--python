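"""Pipeline orchestration: the per-partition summary table, the RF dendrogram,
concordance annotation, the saturation tables and the variance decomposition
explaining RF distance.

``run_pipeline`` ties everything together from a YAML configuration and
writes CSV/Newick deliverables only; figure rendering is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
import yaml

from . import __version__
from .alignment import Alignment, read_fasta_alignment, read_partition_file, sic, count_parsimony_informative
from .congruence import (
    annotate_reference,
    gene_concordance_factor,
    neighbor_joining,
    rf_distance,
    rf_matrix,
    site_concordance_factor,
)
from .likelihood import SubstitutionModel, sh_test
from .saturation import saturation_regression
from .simulate import SimulationConfig, evolve_alignment, simulate_tree
from .treeio import (
    PhyloTree,
    count_bifurcating_nodes,
    count_polytomy_branches,
    mean_node_support,
    read_tree,
    write_newick,
)

logger = logging.getLogger(__name__)

__all__ = ["MetricsRow", "build_summary", "explain_rf_anova", "run_pipeline"]

SUMMARY_COLUMNS = [
    "partition",
    "polytomy_branches",
    "saturation_slope",
    "mean_node_support",
    "bifurcating_nodes",
    "alignment_length_bp",
    "pi_sites",
    "sic",
    "rf_from_reference",
    "sh_p_value",
]


@dataclass
class MetricsRow:
    """One partition's full congruence record (one row of the summary table)."""

    partition: str
    polytomy_branches: Optional[int] = None
    saturation_slope: Optional[float] = None
    mean_node_support: Optional[float] = None
    bifurcating_nodes: Optional[int] = None
    alignment_length_bp: Optional[int] = None
    pi_sites: Optional[int] = None
    sic: Optional[float] = None
    rf_from_reference: Optional[int] = None
    sh_p_value: Optional[float] = None


def build_summary(
    reference: PhyloTree,
    genes: Dict[str, Tuple[PhyloTree, Alignment]],
    reference_alignment: Optional[Alignment] = None,
    reference_label: str = "reference",
    correction_model: str = "JC69",
    max_excluded_fraction: float = 0.25,
    sh_p_values: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """Assemble the per-partition summary table (reference row first).

    Saturation slopes are reported only when at most ``max_excluded_fraction``
    of taxon pairs have undefined corrected distances (gap-rich markers are
    skipped rather than inflated). Per-gene failures yield nulls in that row
    and a logged diagnostic; the pipeline continues.
    """
    sh_p_values = sh_p_values or {}
    rows: List[MetricsRow] = []

    def metrics_for(name: str, tree: PhyloTree, aln: Optional[Alignment]) -> MetricsRow:
        row = MetricsRow(partition=name)
        try:
            row.polytomy_branches = count_polytomy_branches(tree)
            row.bifurcating_nodes = count_bifurcating_nodes(tree)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("%s: topology metrics failed: %s", name, exc)
        try:
            row.mean_node_support = round(mean_node_support(tree), 3)
        except Exception as exc:
            logger.info("%s: no node supports (%s)", name, exc)
        try:
            row.rf_from_reference = rf_distance(reference, tree)
        except Exception as exc:
            logger.warning("%s: RF distance failed: %s", name, exc)
        if aln is not None:
            row.alignment_length_bp = aln.length
            row.pi_sites = count_parsimony_informative(aln)
            row.sic = sic(aln)
            try:
                sat = saturation_regression(aln, model=correction_model, gene_id=name)
                n_total = sat.n_pairs + sat.n_excluded_pairs
                if sat.n_excluded_pairs <= max_excluded_fraction * n_total:
                    row.saturation_slope = round(sat.slope, 3)
                else:
                    logger.info(
                        "%s: saturation skipped (%d/%d pairs undefined)",
                        name, sat.n_excluded_pairs, n_total,
                    )
            except ValueError as exc:
                logger.info("%s: saturation skipped (%s)", name, exc)
        row.sh_p_value = sh_p_values.get(name)
        return row

    rows.append(metrics_for(reference_label, reference, reference_alignment))
    for name, (tree, aln) in genes.items():
        rows.append(metrics_for(name, tree, aln))
    return pd.DataFrame([asdict(r) for r in rows], columns=SUMMARY_COLUMNS)


def explain_rf_anova(
    summary: pd.DataFrame,
    terms: Sequence[str] = (
        "saturation_slope",
        "alignment_length_bp",
        "alignment_length_bp:pi_sites",
    ),
    reference_label: str = "reference",
) -> pd.DataFrame:
    """Sequential (Type-I) ANOVA of RF distance on the ordered terms.

    Default terms are saturation slope, alignment length, and the
    length-by-informative-sites interaction; topology-derived metrics
    (polytomies, bifurcating nodes, mean support) are deliberately omitted
    because they are intrinsically linked to RF distance. The reference row
    is excluded. Term order matters for sequential sums of squares.
    """
    data = summary[summary["partition"] != reference_label].copy()
    base_vars = sorted({v for t in terms for v in t.split(":")})
    data = data.dropna(subset=["rf_from_reference"] + base_vars)
    if len(data) < len(terms) + 2:
        raise ValueError(
            f"need at least {len(terms) + 2} complete rows, have {len(data)}"
        )
    for var in base_vars:
        if np.ptp(data[var].to_numpy(dtype=float)) == 0:
            raise ValueError(f"predictor {var!r} is constant")
    formula = "rf_from_reference ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    table.index.name = "term"
    return table


def _collect_sh(
    alignment: Alignment,
    trees: Dict[str, PhyloTree],
    model: SubstitutionModel,
    n_replicates: int,
    seed: int,
) -> Tuple[Dict[str, float], pd.DataFrame]:
    result = sh_test(alignment, trees, model, n_replicates=n_replicates, seed=seed)
    frame = result.to_frame()
    return dict(zip(result.tree_ids, result.p_values)), frame


def _model_from_config(block: dict) -> SubstitutionModel:
    return SubstitutionModel(
        exchangeabilities=tuple(block.get("exchangeabilities", (1,) * 6)),
        base_freqs=tuple(block.get("base_freqs", (0.25,) * 4)),
        p_invariant=float(block.get("p_invariant", 0.0)),
        gamma_shape=block.get("gamma_shape"),
        n_categories=int(block.get("n_categories", 4)),
    )


def run_pipeline(config_path) -> Path:
    """Run the full congruence pipeline from a YAML configuration.

    The config names a reference tree, per-gene trees and alignments (or a
    ``simulate`` block that generates them), substitution-model settings and
    a seed. All deliverables are written to the configured output directory:
    summary.csv, rf_matrix.{csv,phy}, dendrogram.nwk, reference_annotated.nwk,
    concordance.csv, length_vs_rf.csv, saturation/*.csv, sh_test.csv,
    anova.csv and run.log.
    """
    config_path = Path(config_path)
    config = yaml.safe_load(config_path.read_text())
    outdir = Path(config.get("output_dir", "mitoconcord_output"))
    outdir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mitoconcord")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, config_path, outdir)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _load_inputs(config: dict, config_dir: Path):
    seed = config.get("seed")
    if seed is None:
        raise ValueError("config must set a seed")

    if "simulate" in config:
        sim = config["simulate"]
        sim_config = SimulationConfig(
            seed=seed,
            n_taxa=int(sim.get("n_taxa", 12)),
            tree_model=sim.get("tree_model", "yule"),
            birth_rate=float(sim.get("birth_rate", 1.0)),
            death_rate=float(sim.get("death_rate", 0.0)),
            tree_height_scale=sim.get("tree_height_scale"),
            min_branch_length=sim.get("min_branch_length"),
            partition_spec={k: int(v) for k, v in sim["partitions"].items()},
            model=_model_from_config(sim.get("model", {})),
            rate_multipliers={
                k: float(v) for k, v in sim.get("rate_multipliers", {}).items()
            },
        )
        rng = np.random.default_rng(seed)
        reference = simulate_tree(sim_config, rng)
        full_aln = evolve_alignment(reference, sim_config, rng)
        from .simulate import estimate_tree_nj

        genes: Dict[str, Tuple[PhyloTree, Alignment]] = {}
        for name in sim_config.partition_spec:
            part = full_aln.partition(name)
            genes[name] = (estimate_tree_nj(part), part)
        return reference, full_aln, genes

    problems = []
    ref_path = config_dir / config.get("reference_tree", "")
    if not config.get("reference_tree"):
        problems.append("reference_tree not set")
    elif not ref_path.exists():
        problems.append(f"reference tree missing: {ref_path}")
    ref_aln_path = config.get("reference_alignment")
    if ref_aln_path and not (config_dir / ref_aln_path).exists():
        problems.append(f"reference alignment missing: {ref_aln_path}")
    gene_specs = config.get("genes", {})
    if not gene_specs:
        problems.append("no genes configured")
    for name, spec in gene_specs.items():
        for key in ("tree", "alignment"):
            p = spec.get(key)
            if not p:
                problems.append(f"gene {name}: {key} not set")
            elif not (config_dir / p).exists():
                problems.append(f"gene {name}: {key} missing: {p}")
    if problems:
        raise FileNotFoundError("invalid pipeline inputs: " + "; ".join(problems))

    reference = read_tree(ref_path)
    full_aln = (
        read_fasta_alignment(config_dir / ref_aln_path) if ref_aln_path else None
    )
    if full_aln is not None and config.get("partition_file"):
        full_aln.partition_map.update(
            read_partition_file(config_dir / config["partition_file"])
        )
    genes = {
        name: (
            read_tree(config_dir / spec["tree"]),
            read_fasta_alignment(config_dir / spec["alignment"]),
        )
        for name, spec in gene_specs.items()
    }
    return reference, full_aln, genes


def _run_pipeline(config: dict, config_path: Path, outdir: Path) -> Path:
    seed = config["seed"] if "seed" in config else None
    reference, full_aln, genes = _load_inputs(config, config_path.parent)
    reference_label = config.get("reference_label", "reference")
    correction_model = config.get("correction_model", "JC69")
    model = _model_from_config(config.get("model", config.get("simulate", {}).get("model", {})))

    logger.info("mitoconcord %s | config %s | seed %s", __version__, config_path, seed)
    logger.info("reference: %d leaves; %d gene partitions", reference.n_leaves, len(genes))

    # SH test of all topologies against the reference alignment
    sh_p: Dict[str, float] = {}
    sh_frame = None
    sh_cfg = config.get("sh_test", {})
    if sh_cfg.get("enabled", True) and full_aln is not None:
        candidates = {reference_label: reference}
        candidates.update({name: tree for name, (tree, _) in genes.items()})
        sh_p, sh_frame = _collect_sh(
            full_aln,
            candidates,
            model,
            n_replicates=int(sh_cfg.get("n_replicates", 1000)),
            seed=seed,
        )

    summary = build_summary(
        reference,
        genes,
        reference_alignment=full_aln,
        reference_label=reference_label,
        correction_model=correction_model,
        sh_p_values=sh_p,
    )
    summary.to_csv(outdir / "summary.csv", index=False)

    # RF matrix over all trees and the NJ dendrogram of topologies
    all_trees = {reference_label: reference}
    all_trees.update({name: tree for name, (tree, _) in genes.items()})
    matrix = rf_matrix(all_trees)
    matrix.to_frame().to_csv(outdir / "rf_matrix.csv")
    matrix.write_phylip(outdir / "rf_matrix.phy")
    dendrogram = neighbor_joining(matrix)
    (outdir / "dendrogram.nwk").write_text(write_newick(dendrogram) + "\n")

    # concordance factors on the reference tree
    gene_tree_list = [tree for tree, _ in genes.values()]
    gcf = gene_concordance_factor(reference, gene_tree_list)
    annotations = {a.branch: a for a in gcf}
    if full_aln is not None:
        scf_cfg = config.get("scf", {})
        scf = site_concordance_factor(
            reference,
            full_aln,
            n_quartets=int(scf_cfg.get("n_quartets", 100)),
            seed=seed,
        )
        for a in scf:
            if a.branch in annotations:
                annotations[a.branch].scf = a.scf
                annotations[a.branch].n_quartets_sampled = a.n_quartets_sampled
                annotations[a.branch].n_decisive_quartets = a.n_decisive_quartets
    ann_list = list(annotations.values())
    pd.DataFrame(
        {
            "branch": [repr(a.branch) for a in ann_list],
            "gcf": [a.gcf for a in ann_list],
            "scf": [a.scf for a in ann_list],
            "n_gene_trees": [a.n_gene_trees for a in ann_list],
            "n_decisive_trees": [a.n_decisive_trees for a in ann_list],
            "n_quartets_sampled": [a.n_quartets_sampled for a in ann_list],
            "n_decisive_quartets": [a.n_decisive_quartets for a in ann_list],
        }
    ).to_csv(outdir / "concordance.csv", index=False)
    annotated = annotate_reference(reference, ann_list)
    (outdir / "reference_annotated.nwk").write_text(write_newick(annotated) + "\n")

    # length-vs-RF scatter data
    gene_rows = summary[summary["partition"] != reference_label]
    gene_rows[["partition", "alignment_length_bp", "rf_from_reference"]].to_csv(
        outdir / "length_vs_rf.csv", index=False
    )

    # per-gene saturation scatter data
    satdir = outdir / "saturation"
    satdir.mkdir(exist_ok=True)
    for name, (_, aln) in genes.items():
        try:
            sat = saturation_regression(aln, model=correction_model, gene_id=name)
        except ValueError as exc:
            logger.info("saturation scatter skipped for %s: %s", name, exc)
            continue
        x, y = sat.scatter_data()
        pd.DataFrame({"corrected_dist": x, "p_dist": y}).to_csv(
            satdir / f"{name}.csv", index=False
        )

    if sh_frame is not None:
        sh_frame.to_csv(outdir / "sh_test.csv", index=False)

    try:
        anova = explain_rf_anova(summary, reference_label=reference_label)
        anova.to_csv(outdir / "anova.csv")
    except ValueError as exc:
        logger.warning("ANOVA skipped: %s", exc)

    logger.info("pipeline complete; outputs in %s", outdir)
    return outdir
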