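"""End-to-end orchestration: simulate -> harmonize -> select -> modules
-> CrossBoruta -> network metrics -> report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import harmonize, io, modules, network, synthetic
from .boruta import BorutaConfig, boruta_ensemble, evaluate_prediction

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of one pipeline run; serializable, hashed into every
    output's provenance."""

    seed: int = 0
    outdir: str = "crossage_run"
    # simulate stage (ignored when expression/samples paths are given)
    simulate: bool = True
    expression_path: str | None = None
    samples_path: str | None = None
    n_genes: int = 120
    organs: list[str] = field(default_factory=lambda: list(synthetic.DEFAULT_ORGANS[:3]))
    replicates_per_cell: int = 3
    variance_fractions: dict[str, float] = field(
        default_factory=lambda: dict(synthetic.DEFAULT_VARIANCE_FRACTIONS)
    )
    n_per_archetype: int = 8
    n_regulators: int = 1
    targets_per_regulator: int = 8
    # harmonize stage
    search_correction_order: bool = False
    correction_plan: list[list[str]] = field(
        default_factory=lambda: [["organ", "combat"], ["strain", "combat"], ["sex", "zscore"]]
    )
    pvca_threshold: float = 0.6
    # selection stage
    n_trees: int = 120
    max_runs: int = 25
    alpha: float = 0.01
    n_iterations: int = 3
    run_cva: bool = True
    # modules stage
    power_threshold: float = 0.94
    default_power: int = 5  # used when the scale-free threshold is unmet
    min_module_size: int = 8
    split_threshold: float = 0.22
    # crossboruta stage
    crossboruta_iterations: int = 1
    eval_folds: int = 5

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def union_hits(nva, cva) -> pd.Series:
    """Union of the two mode-specific hit sets with origin labels
    (NVA / CVA / both). Both ensembles must share a gene universe."""
    nva_univ = set(nva.n_nonrejected.index)
    cva_univ = set(cva.n_nonrejected.index)
    if nva_univ != cva_univ:
        raise ValueError("NVA and CVA ensembles cover different gene universes")
    a, b = set(nva.hit_set), set(cva.hit_set)
    origin = {}
    for g in a | b:
        origin[g] = "both" if (g in a and g in b) else ("NVA" if g in a else "CVA")
    return pd.Series(origin, name="origin").sort_index()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write artifacts under ``config.outdir`` and
    return the run report (also written as report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    report: dict = {"config_hash": chash, "seed": config.seed}

    # --- inputs -----------------------------------------------------------
    if config.expression_path and config.samples_path:
        expr = io.read_expression_tsv(config.expression_path)
        samples = io.read_samples_tsv(config.samples_path)
        truth = None
    elif config.simulate:
        design = synthetic.CohortDesign(
            organs=config.organs, replicates_per_cell=config.replicates_per_cell,
            seed=config.seed,
        )
        structure = synthetic.default_planted_structure(
            n_genes=config.n_genes,
            variance_fractions=config.variance_fractions,
            n_per_archetype=config.n_per_archetype,
            n_regulators=config.n_regulators,
            targets_per_regulator=config.targets_per_regulator,
        )
        cohort = synthetic.generate_cohort(design, structure)
        cohort.write(outdir / "cohort")
        expr, samples, truth = cohort.expression, cohort.samples, cohort.truth
    else:
        raise ValueError("either provide expression/samples paths or enable simulate")
    report["n_genes"] = int(expr.shape[0])
    report["n_samples"] = int(expr.shape[1])

    # --- harmonize --------------------------------------------------------
    factors = ["organ", "strain", "sex", "age"]
    pvca_raw = harmonize.pvca(expr, samples, factors, config.pvca_threshold)
    if config.search_correction_order:
        ranked = harmonize.search_order(expr, samples, ["organ", "strain", "sex"])
        plan = ranked[0][0]
        report["plans_evaluated"] = len(ranked)
    else:
        plan = harmonize.CorrectionPlan.from_pairs(
            [(c, m) for c, m in config.correction_plan]
        )
    corrected = harmonize.apply_plan(expr, samples, plan)
    pvca_corr = harmonize.pvca(corrected, samples, factors, config.pvca_threshold)
    report["correction_plan"] = plan.describe()
    report["pvca_raw"] = pvca_raw.fractions
    report["pvca_corrected"] = pvca_corr.fractions
    io.write_expression_tsv(corrected, outdir / "corrected.tsv")

    # --- age selection (NVA / CVA) ---------------------------------------
    Xp = corrected.T  # samples x genes
    age = samples["age_months"]
    base = BorutaConfig(
        n_trees=config.n_trees, max_runs=config.max_runs, alpha=config.alpha,
        n_iterations=config.n_iterations, seed=config.seed,
    )
    nva = boruta_ensemble(Xp, age.to_numpy(dtype=float), base)
    nva.to_frame().to_csv(outdir / "boruta_nva.tsv", sep="\t")
    if config.run_cva:
        from dataclasses import replace

        cva = boruta_ensemble(Xp, age.astype(str).to_numpy(),
                              replace(base, mode="categorical", seed=config.seed + 1))
        cva.to_frame().to_csv(outdir / "boruta_cva.tsv", sep="\t")
    else:
        cva = nva
    origin = union_hits(nva, cva)
    if not config.run_cva:
        origin[:] = "NVA"
    origin.rename_axis("gene").to_frame().to_csv(outdir / "hits.tsv", sep="\t")
    hits = list(origin.index)
    report["n_hits_nva"] = len(nva.hit_set)
    report["n_hits_cva"] = len(cva.hit_set) if config.run_cva else 0
    report["n_hits_union"] = len(hits)
    report["n_hits_overlap"] = (
        report["n_hits_nva"] + report["n_hits_cva"] - len(hits) if config.run_cva else 0
    )

    # --- predictive utility ----------------------------------------------
    if hits:
        ev_all = evaluate_prediction(Xp, age.to_numpy(dtype=float), None, "numeric",
                                     folds=config.eval_folds, seed=config.seed)
        ev_sel = evaluate_prediction(Xp, age.to_numpy(dtype=float), hits, "numeric",
                                     folds=config.eval_folds, seed=config.seed)
        report["accuracy_all_features"] = ev_all.accuracy
        report["kappa_all_features"] = ev_all.kappa
        report["accuracy_hit_set"] = ev_sel.accuracy
        report["kappa_hit_set"] = ev_sel.kappa

    # --- modules ----------------------------------------------------------
    module_labels = pd.Series(dtype=object)
    if len(hits) >= config.min_module_size:
        sub = corrected.loc[hits]
        scan = modules.pick_power(sub, threshold=config.power_threshold)
        # small networks inflate the fit index at extreme powers; fall
        # back to the configured default when the threshold is unmet
        beta = scan.chosen_power if scan.threshold_met else config.default_power
        mods = modules.detect_modules(sub, beta,
                                      min_module_size=config.min_module_size)
        module_labels = mods.membership
        mods.membership.rename_axis("gene").to_frame("module").to_csv(
            outdir / "modules.tsv", sep="\t"
        )
        mods.eigengenes.rename_axis("sample").to_csv(outdir / "eigengenes.tsv", sep="\t")
        scan.to_frame().to_csv(outdir / "power_scan.tsv", sep="\t", index=False)
        report["chosen_power"] = beta
        report["power_threshold_met"] = scan.threshold_met
        report["n_modules"] = len(mods.modules)
        splits = {}
        for mod in mods.modules:
            members = mods.membership.index[mods.membership == mod]
            if len(members) >= 4:
                sp = modules.split_antiparallel(
                    corrected.loc[members], samples,
                    distance_threshold=config.split_threshold, module=mod,
                )
                splits[mod] = {
                    "antiparallel": sp.antiparallel,
                    "profile_correlation": sp.profile_correlation,
                }
        report["module_splits"] = splits

    # --- crossboruta + aging network --------------------------------------
    if hits:
        from dataclasses import replace

        cb_cfg = replace(base, n_iterations=config.crossboruta_iterations,
                         mode="numeric", seed=config.seed)
        table = network.crossboruta(corrected, hits, cb_cfg)
        table.write_tsv(outdir / "edges.tsv")
        report["n_edges_full"] = len(table)
        net = network.restrict_to_hits(
            table, hits, modules=module_labels if len(module_labels) else None,
            origins=origin,
        )
        report["n_edges_restricted"] = net.n_edges
        net.node_table.to_csv(outdir / "nodes.tsv", sep="\t")
        network.export_network(net, outdir / "aging_network.graphml")
        defined = net.node_table.loc[net.node_table["AAS_defined"], "AAS_log2"]
        report["n_aas_defined"] = int(net.node_table["AAS_defined"].sum())
        report["closeness_q90"] = (
            network.quantile_threshold(net.node_table["closeness"], 0.90)
            if len(net.node_table) else None
        )
        report["median_aas_log2"] = float(np.median(defined)) if len(defined) else None
        if truth is not None and truth.regulators:
            regs = [r for r, _t, _e in truth.regulators if r in net.node_table.index]
            report["regulator_aas_log2"] = {
                r: (None if not net.node_table.loc[r, "AAS_defined"]
                    else float(net.node_table.loc[r, "AAS_log2"]))
                for r in regs
            }
            report["regulator_hub_scores"] = {
                r: int(net.node_table.loc[r, "hub_score"]) for r in regs
            }

    io.write_json(report, outdir / "report.json")
    logger.info("pipeline run %s complete: %d hits, %s edges",
                chash, len(hits), report.get("n_edges_restricted"))
    return report
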