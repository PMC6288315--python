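"""End-to-end orchestration: simulate/load -> DE -> RIF -> co-expression
-> network -> qPCR validation, with derived per-stage seeds and a
machine-readable run report.

Stage seeds are derived from the master seed and a fixed stage index,
so re-running a single stage reproduces the values it had inside a full
run, and adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import ConsistencyError, ExpressionMatrix
from .de import DEThresholds, de_screen, group_stats
from .io import (read_annotation, read_expression_matrix, read_phenotype,
                 write_annotation, write_expression_matrix, write_metadata)
from .coexpr import (annotate_cis, correlation_bootstrap_ci,
                     lnc_gene_correlations, mark_significant)
from .network import (build_network, hub_lncrnas, intramodular_connectivity,
                      module_eigengene, module_trait_correlation, UNASSIGNED)
from .qpcr import (QPCRTable, lin_ccc, normalization_factors,
                   per_gene_platform_correlation, relative_quantities)
from .rif import expressed_features, extreme_counts, rif_analysis
from .simulate import SimConfig, simulate_experiment, simulate_qpcr

log = logging.getLogger(__name__)

_STAGE_INDEX = {"simulate": 0, "de": 1, "rif": 2, "coexpr": 3,
                "wgcna": 4, "validate": 5}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence((int(master_seed), _STAGE_INDEX[stage]))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Settings for a full pipeline run.

    Either ``sim`` (synthetic experiment) or the three input paths must
    be provided.
    """

    sim: SimConfig | None = None
    matrix_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    rif_n_iter: int = 1_000
    rif_level: float = 0.99
    rif_scale: str = "log2p1"
    coexpr_n_iter: int = 1_000
    coexpr_level: float = 0.95
    beta: int = 6
    min_module_size: int = 3
    cut_quantile: float = 0.95
    top_fraction: float = 0.20
    run_qpcr: bool = True
    qpcr_panel_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and self.matrix_path is None:
            raise ValueError("config needs either 'sim' or input paths")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "sim" in raw and raw["sim"] is not None:
            sim = dict(raw["sim"])
            if "module_spec" in sim:
                from .simulate import ModuleSpec
                sim["module_spec"] = tuple(
                    ModuleSpec(*m) if not isinstance(m, ModuleSpec) else m
                    for m in sim["module_spec"])
            raw["sim"] = SimConfig(**sim)
        if "thresholds" in raw and raw["thresholds"] is not None \
                and not isinstance(raw["thresholds"], DEThresholds):
            raw["thresholds"] = DEThresholds(**raw["thresholds"])
        return cls(**raw)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage, write outputs under ``out_dir``, return the
    run report (also written as ``report.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "version": __version__,
                    "counts": {}, "settings": _settings_echo(config),
                    "timing": {}}
    timings = report["timing"]

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", stage)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[stage] = time.perf_counter() - self.t0
                if exc_type is not None:
                    log.error("stage %s failed: %s", stage, exc)
                    raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
                log.info("stage %s: done (%.2fs)", stage, timings[stage])
        return _T()

    truth = None
    with timed("simulate" if config.sim else "load"):
        if config.sim is not None:
            sim = config.sim.with_(seed=stage_seed(config.seed, "simulate"))
            matrix, annotation, phenotype, truth = simulate_experiment(sim)
            write_expression_matrix(matrix, out / "matrix.tsv")
            write_metadata(matrix.groups, out / "metadata.tsv",
                           imf=phenotype["imf"])
            write_annotation(annotation, out / "annotation.bed")
            _dump_json(truth.to_jsonable(), out / "truth.json")
        else:
            matrix = read_expression_matrix(config.matrix_path,
                                            config.metadata_path)
            annotation = read_annotation(config.annotation_path)
            try:
                phenotype = read_phenotype(config.metadata_path, matrix)
            except Exception:
                phenotype = None
    biotypes = annotation["biotype"]
    expressed = expressed_features(matrix, config.thresholds.min_group_fpkm)
    report["counts"]["features"] = int(len(matrix.feature_ids))
    report["counts"]["expressed"] = int(len(expressed))

    with timed("de"):
        de_table = de_screen(matrix, config.thresholds)
        de_table.index.name = "feature_id"
        de_table.to_csv(out / "de.tsv", sep="\t", float_format="%.10g")
        de_all = de_table.index[de_table["is_DE"]]
        de_genes = [f for f in de_all if biotypes.get(f) == "coding"]
        de_lncs = [f for f in de_all if biotypes.get(f) == "lncRNA"]
        report["counts"]["de_total"] = int(len(de_all))
        report["counts"]["de_genes"] = int(len(de_genes))
        report["counts"]["de_lncRNAs"] = int(len(de_lncs))
        for flag in ("pass_expression", "pass_fc", "pass_significance"):
            report["counts"][flag] = int(de_table[flag].sum())

    trf_ids = [f for f in matrix.feature_ids if biotypes.get(f) == "TRF"]
    with timed("rif"):
        if de_genes and trf_ids:
            excluded = set(trf_ids) | set(de_genes)
            pool = [f for f in expressed
                    if biotypes.get(f) == "coding" and f not in excluded]
            rif_table, null1, null2 = rif_analysis(
                matrix, de_genes, trf_ids, pool_ids=pool,
                n_iter=config.rif_n_iter, level=config.rif_level,
                seed=stage_seed(config.seed, "rif"), scale=config.rif_scale,
                min_fpkm=config.thresholds.min_group_fpkm)
            rif_table.to_csv(out / "rif.tsv", sep="\t", float_format="%.10g")
            _dump_json({"rif1": null1.to_jsonable(),
                        "rif2": null2.to_jsonable()}, out / "rif_null.json")
            report["counts"]["extreme_trfs"] = extreme_counts(rif_table)
        else:
            log.warning("rif stage skipped (no DE genes or no TRFs)")
            report["counts"]["extreme_trfs"] = None

    with timed("coexpr"):
        lnc_pool = [f for f in expressed if biotypes.get(f) == "lncRNA"]
        gene_pool = [f for f in expressed if biotypes.get(f) == "coding"]
        sig_lncs: list[str] = []
        if lnc_pool and de_genes:
            records = lnc_gene_correlations(matrix, lnc_pool, de_genes)
            null = correlation_bootstrap_ci(
                matrix, lnc_pool, gene_pool, n_iter=config.coexpr_n_iter,
                level=config.coexpr_level,
                seed=stage_seed(config.seed, "coexpr"))
            records = annotate_cis(mark_significant(records, null), annotation)
            records.to_csv(out / "coexpr.tsv", sep="\t", index=False,
                           float_format="%.10g")
            _dump_json(null.to_jsonable(), out / "coexpr_null.json")
            sig = records[records["significant"]]
            sig_lncs = sorted(sig["lnc_id"].unique())
            report["counts"]["significant_pairs"] = int(len(sig))
            report["counts"]["significant_lncRNAs"] = int(len(sig_lncs))
        else:
            log.warning("coexpr stage skipped (no expressed lncRNAs or DE genes)")
            report["counts"]["significant_pairs"] = None

    with timed("wgcna"):
        net_ids = sorted(set(de_genes) | set(sig_lncs))
        if len(net_ids) >= 2 * config.min_module_size:
            if phenotype is None or "imf" not in phenotype.columns:
                raise ConsistencyError(
                    "module-trait stage requires the metadata 'imf' column")
            net = build_network(matrix, net_ids, beta=config.beta,
                                min_size=config.min_module_size,
                                cut_quantile=config.cut_quantile)
            eigengenes = {}
            summaries = {}
            for label in sorted(set(net.module_labels) - {UNASSIGNED}):
                members = net.module_labels.index[net.module_labels == label]
                eig, var_exp = module_eigengene(matrix, members)
                eigengenes[label] = eig
                summaries[label] = {"size": int(len(members)),
                                    "variance_explained": var_exp}
            kim = intramodular_connectivity(net.adjacency, net.module_labels)
            hubs = hub_lncrnas(kim, net.module_labels, biotypes,
                               config.top_fraction)
            if eigengenes:
                trait = module_trait_correlation(eigengenes, phenotype)
                for label in summaries:
                    summaries[label]["trait_cor"] = float(
                        trait.loc[label, "trait_cor"])
                    summaries[label]["trait_p"] = float(
                        trait.loc[label, "trait_p"])
                    summaries[label]["hub_lncRNAs"] = sorted(hubs.get(label, ()))
            modules_out = pd.DataFrame({"module": net.module_labels,
                                        "kIM": kim})
            modules_out.index.name = "feature_id"
            modules_out.to_csv(out / "modules.tsv", sep="\t",
                               float_format="%.10g")
            _dump_json(summaries, out / "module_summary.json")
            report["counts"]["modules"] = int(len(summaries))
            report["counts"]["hub_lncRNAs"] = int(sum(len(h)
                                                      for h in hubs.values()))
        else:
            log.warning("wgcna stage skipped (too few network features)")
            report["counts"]["modules"] = None

    with timed("validate"):
        if config.run_qpcr and config.sim is not None:
            val = _qpcr_validation(matrix, de_table, config, sim)
            val["per_gene"].to_csv(out / "validation.tsv", sep="\t",
                                   float_format="%.10g")
            _dump_json(val["summary"], out / "validation_summary.json")
            report["counts"]["validation"] = val["summary"]
        else:
            report["counts"]["validation"] = None

    _dump_json(report, out / "report.json")
    return report


def _qpcr_validation(matrix: ExpressionMatrix, de_table: pd.DataFrame,
                     config: RunConfig, sim: SimConfig) -> dict:
    """Simulated technical validation: a panel of up/down/stable genes
    plus two stable reference genes, run through the qPCR stage."""
    stats = de_table.sort_values("log2fc")
    expressed = stats[(stats[["mean_H", "mean_L"]].max(axis=1) >= 1.0)]
    de = expressed[expressed["is_DE"]]
    stable = expressed[~expressed["is_DE"]].copy()
    stable["abs_fc"] = stable["log2fc"].abs()
    stable = stable.sort_values(["abs_fc", "mean_H"])
    k = max(1, config.qpcr_panel_size // 3)
    up = list(de.index[-k:])
    down = list(de.index[:k])
    panel = down + up + [g for g in stable.index[:k] if g not in up + down]
    refs = [g for g in stable.index if g not in panel][:2]
    if len(refs) < 2:
        raise ConsistencyError("not enough stable genes for qPCR references")
    cp, eff = simulate_qpcr(matrix, panel + refs,
                            sim.with_(seed=stage_seed(config.seed, "validate")),
                            reference_genes=refs)
    table = QPCRTable(cp=cp, efficiency=eff, reference_genes=refs)
    q = relative_quantities(table)
    nf = normalization_factors(q, refs)
    normalized = q / nf
    per_gene = per_gene_platform_correlation(
        matrix.values.loc[panel], normalized.loc[panel])
    # fold-change agreement between platforms
    pc = config.thresholds.pseudocount
    h = matrix.samples_in_group("H")
    l = matrix.samples_in_group("L")
    fc_qpcr = np.log2((normalized.loc[panel, h].mean(axis=1) + pc)
                      / (normalized.loc[panel, l].mean(axis=1) + pc))
    fc_rnaseq = de_table.loc[panel, "log2fc"]
    ccc = lin_ccc(fc_rnaseq.to_numpy(), fc_qpcr.to_numpy())
    per_gene = per_gene.assign(log2fc_rnaseq=fc_rnaseq,
                               log2fc_qpcr=fc_qpcr)
    per_gene.index.name = "gene"
    return {"per_gene": per_gene,
            "summary": {"ccc": ccc.ccc, "pearson_fc": ccc.pearson,
                        "n_panel": len(panel),
                        "reference_genes": refs}}


def _settings_echo(config: RunConfig) -> dict:
    from dataclasses import asdict
    echo = asdict(config)
    return json.loads(json.dumps(echo, default=str))
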