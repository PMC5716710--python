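"""End-to-end orchestration: differential filter -> correlation -> ceRNA calls.

Mirrors the study workflow: restrict to differentially expressed features,
pair differentially expressed miRNAs with targets by negative correlation,
intersect with the sequence-predicted pair list, score lncRNA-mRNA
candidates with the shared-miRNA hypergeometric test, intersect with
lncRNA-mRNA co-expression, and export the resulting networks. The run
summary reports the count chain of every stage (the Venn-diagram panel as
numbers) and is byte-identical for identical configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import cerna, correlation, network, quant, simulate
from .errors import ConfigError, CernaTriadError

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All thresholds of the inference chain, with study defaults."""

    fc_threshold: float | None = 2.0
    alpha: float = 0.05
    use_adjusted: bool = False
    r_threshold: float = 0.7
    p_threshold: float = 0.05
    coexpression_mode: str = "absolute"
    min_shared: int = 1
    cerna_p: float | None = 0.05
    M_T: int | None = None  # default: number of DE miRNAs in the run


@dataclass
class RunConfig:
    """File-level configuration for a full run.

    Either ``expr``/``groups``/``predicted_pairs`` point at existing inputs,
    or ``simulate`` holds :class:`~cerna_triad.simulate.SimulationConfig`
    fields and the inputs are generated into ``outdir`` first.
    """

    outdir: str = "cerna_run"
    expr: str | None = None
    groups: str | None = None
    predicted_pairs: str | None = None
    simulate: dict | None = None
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = PipelineParams(**raw.pop("params", {}))
        cfg = cls(**{**raw, "params": params})
        if cfg.simulate is None:
            for key in ("expr", "groups", "predicted_pairs"):
                p = getattr(cfg, key)
                if p is None:
                    raise ConfigError(f"config must set {key!r} (or a 'simulate' section)")
                if not Path(p).exists():
                    raise ConfigError(f"input file for {key!r} does not exist: {p}")
        return cfg


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    summary: dict
    de_tables: dict[str, pd.DataFrame]
    shared_mirna_mrna: list[correlation.CorrelationEdge]
    shared_mirna_lncrna: list[correlation.CorrelationEdge]
    predicted_cernas: list[cerna.CeRNACandidate]
    calculated_edges: list[correlation.CorrelationEdge]
    called_cernas: list[cerna.CeRNACandidate]
    net: network.CeRNANetwork


def _stage(name: str, fn, *args, **kwargs):
    try:
        out = fn(*args, **kwargs)
    except CernaTriadError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise CernaTriadError(f"stage {name!r} failed: {exc}") from exc
    return out


def run(matrix: quant.ExpressionMatrix, predicted_pairs, params: PipelineParams | None = None) -> PipelineResult:
    """Run the inference chain in memory and return every intermediate.

    ``predicted_pairs`` is the sequence-predicted miRNA->target list
    (both target classes mixed); ``params`` carries all thresholds.
    """
    params = params or PipelineParams()
    predicted_pairs = cerna.dedupe_pairs(predicted_pairs)

    # 1. differential filter, per class
    de = _stage(
        "differential", quant.differential_table, matrix,
        fc_threshold=params.fc_threshold, alpha=params.alpha, use_adjusted=params.use_adjusted,
    )
    de_tables = {cls: de[de["class"] == cls].reset_index(drop=True) for cls in quant.RNA_CLASSES}
    de_sets = {
        cls: set(t.loc[t["direction"] != "NotSignificant", "feature_id"]) for cls, t in de_tables.items()
    }
    logger.info(
        "differential: %d mRNA, %d miRNA, %d lncRNA features pass",
        len(de_sets["mRNA"]), len(de_sets["miRNA"]), len(de_sets["lncRNA"]),
    )

    summary: dict = {}
    for cls, table in de_tables.items():
        counts = table["direction"].value_counts()
        summary[f"de_{cls}_up"] = int(counts.get("Up", 0))
        summary[f"de_{cls}_down"] = int(counts.get("Down", 0))
        summary[f"de_{cls}_total"] = int(len(de_sets[cls]))

    def de_pairs(pairs, cls):
        return [p for p in pairs if p.target_class == cls
                and p.mirna_id in de_sets["miRNA"] and p.target_id in de_sets[cls]]

    result_bits: dict = {}
    for cls, short in (("mRNA", "mrna"), ("lncRNA", "lncrna")):
        seq_pairs = de_pairs(predicted_pairs, cls)
        summary[f"mre_predicted_{short}"] = len(seq_pairs)
        if de_sets["miRNA"] and de_sets[cls]:
            sub = matrix.subset_features(sorted(de_sets["miRNA"] | de_sets[cls]))
            edges = _stage(f"correlate miRNA-{cls}", correlation.correlate_classes, sub, "miRNA", cls)
            expr_pairs = correlation.filter_negative(
                edges, r_threshold=params.r_threshold, p_threshold=params.p_threshold
            )
        else:
            expr_pairs = []
        summary[f"mre_calculated_{short}"] = len(expr_pairs)
        shared_keys = cerna.intersect_pairs([p.key for p in seq_pairs], [e.key for e in expr_pairs])
        shared_edges = sorted((e for e in expr_pairs if e.key in shared_keys), key=lambda e: e.key)
        summary[f"mre_shared_{short}"] = len(shared_edges)
        result_bits[cls] = shared_edges
        logger.info(
            "miRNA-%s pairs: %d predicted, %d calculated, %d shared",
            cls, len(seq_pairs), len(expr_pairs), len(shared_edges),
        )

    # 3. predicted ceRNAs from shared pairs
    M_T = params.M_T if params.M_T is not None else len(de_sets["miRNA"])
    if result_bits["mRNA"] and result_bits["lncRNA"] and M_T > 0:
        predicted_cernas = _stage(
            "predict ceRNAs", cerna.predict_cernas,
            result_bits["mRNA"], result_bits["lncRNA"],
            M_T=M_T, min_shared=params.min_shared, p_threshold=params.cerna_p,
        )
    else:
        predicted_cernas = []
    summary["cerna_predicted"] = len(predicted_cernas)

    # 4. calculated ceRNAs from lncRNA-mRNA co-expression
    if de_sets["lncRNA"] and de_sets["mRNA"]:
        sub = matrix.subset_features(sorted(de_sets["lncRNA"] | de_sets["mRNA"]))
        lm_edges = _stage("correlate lncRNA-mRNA", correlation.correlate_classes, sub, "lncRNA", "mRNA")
        calculated = correlation.filter_coexpressed(
            lm_edges, r_threshold=params.r_threshold, p_threshold=params.p_threshold,
            mode=params.coexpression_mode,
        )
    else:
        calculated = []
    summary["cerna_calculated"] = len(calculated)

    # 5. shared (called) ceRNAs
    called = _stage("call shared ceRNAs", cerna.call_shared_cernas, predicted_cernas, calculated)
    summary["cerna_shared"] = len(called)
    logger.info(
        "ceRNAs: %d predicted, %d calculated, %d shared",
        len(predicted_cernas), len(calculated), len(called),
    )

    net = _stage(
        "network", network.build_tripartite_network,
        called, result_bits["mRNA"], result_bits["lncRNA"], de,
    )
    return PipelineResult(
        summary=summary,
        de_tables=de_tables,
        shared_mirna_mrna=result_bits["mRNA"],
        shared_mirna_lncrna=result_bits["lncRNA"],
        predicted_cernas=predicted_cernas,
        calculated_edges=calculated,
        called_cernas=called,
        net=net,
    )


def run_pipeline(config: RunConfig) -> dict:
    """File-level run: read or simulate inputs, run, write all outputs.

    Returns the summary dict; writes per-stage TSVs, the network tables and
    ``summary.tsv`` / ``summary.json`` under ``config.outdir``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        if config.seed is not None:
            sim_kwargs["seed"] = config.seed
        sim_cfg = simulate.SimulationConfig.from_mapping(sim_kwargs)
        matrix, pairs, truth = simulate.generate_dataset(sim_cfg)
        quant.write_expression(matrix, outdir / "expression.tsv", outdir / "groups.tsv")
        cerna.write_target_pairs(pairs, outdir / "predicted_pairs.tsv")
        simulate.write_truth(truth, outdir / "truth.tsv")
    else:
        matrix = quant.read_expression(config.expr, config.groups)
        pairs = cerna.read_target_pairs(config.predicted_pairs)

    res = run(matrix, pairs, config.params)

    for cls, table in res.de_tables.items():
        quant.write_differential(table, outdir / f"differential_{cls}.tsv")
    correlation.write_edges(res.shared_mirna_mrna, outdir / "shared_mirna_mrna.tsv")
    correlation.write_edges(res.shared_mirna_lncrna, outdir / "shared_mirna_lncrna.tsv")
    correlation.write_edges(res.calculated_edges, outdir / "calculated_lncrna_mrna.tsv")
    cerna.write_candidates(res.predicted_cernas, outdir / "predicted_cernas.tsv")
    cerna.write_candidates(res.called_cernas, outdir / "called_cernas.tsv")
    network.write_network(res.net, outdir / "network")
    write_summary(res.summary, outdir)
    return res.summary


def write_summary(summary: dict, outdir) -> None:
    outdir = Path(outdir)
    items = list(summary.items())  # insertion order = stage order
    pd.DataFrame(items, columns=["metric", "value"]).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(dict(items), fh, indent=2, sort_keys=False)
        fh.write("\n")
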