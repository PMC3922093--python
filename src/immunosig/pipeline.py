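"""End-to-end orchestration of the metastasis-signature analysis.

Stages: (optional) normalization -> univariate DE screen -> bootstrap
R-SVM selection -> probe-to-gene collapse -> GO over-representation ->
signature extraction (selected genes annotated to the configured
immune term) -> below-median counts -> ROC/cutoff -> classification ->
Kaplan-Meier / log-rank on the predicted strata.  Every stage output
is written with a provenance header and the run is reproducible from
the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as iomod
from .classifier import below_median_counts, classify, roc_analysis
from .enrichment import enrichment_table, hypergeom_enrich, map_probes_to_genes
from .errors import PipelineError, ValidationError
from .preprocess import differential_screen, normalize
from .rsvm import RsvmConfig, bootstrap_select
from .survival import km_by_group, logrank_by_group

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression: str = ""
    metadata: str = ""
    annotation: str = ""
    genesets: str = ""
    out_dir: str = "immunosig_run"
    seed: int = 0
    normalize: bool = False  # True: input is raw non-negative intensities
    positive_label: str = "metastatic"
    fc_threshold: float = 2.0
    q_threshold: float = 0.05
    rsvm: RsvmConfig = field(default_factory=RsvmConfig)
    signature_term: str = "GO:0002376"
    signature_probes: tuple[str, ...] | None = None  # explicit override
    classifier_mode: str = "loo"
    cutoff: float | None = None  # None -> Youden-optimal from the ROC sweep
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        rsvm = RsvmConfig(**raw.pop("rsvm", {}))
        cfg = cls(rsvm=rsvm, **raw)
        if cfg.signature_probes is not None:
            cfg.signature_probes = tuple(cfg.signature_probes)
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage_seed(seed: int, index: int) -> int:
    """Derive a per-stage seed from the run seed (hierarchical spawning)."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the machine-readable summary."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.as_dict()

    def header(stage: str) -> str:
        return iomod.provenance_header(stage, seed=config.seed, config=cfg_dict)

    def run_stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    summary: dict = {"seed": config.seed}

    # ---- load inputs -------------------------------------------------
    def _load():
        expr = iomod.read_expression(config.expression)
        meta = iomod.read_metadata(config.metadata)
        if set(meta["sample_id"]) != set(expr.columns):
            raise ValidationError("metadata samples do not match expression columns")
        meta = meta.set_index("sample_id").loc[list(expr.columns)].reset_index()
        annotation = iomod.read_annotation(config.annotation)
        genesets = iomod.read_genesets(config.genesets)
        return expr, meta, annotation, genesets

    expr, meta, annotation, genesets = run_stage("load", _load)
    labels = meta["label"].to_numpy()
    summary["n_samples"] = int(expr.shape[1])
    summary["n_probes"] = int(expr.shape[0])

    # ---- normalize ---------------------------------------------------
    if config.normalize:
        def _normalize():
            norm = normalize(expr)
            iomod.write_expression(norm, out / "normalized.tsv", header("normalize"))
            return norm

        expr = run_stage("normalize", _normalize)

    # ---- univariate DE screen ---------------------------------------
    def _screen():
        de = differential_screen(
            expr,
            labels,
            positive_label=config.positive_label,
            fc_threshold=config.fc_threshold,
            q_threshold=config.q_threshold,
        )
        de_out = de.reset_index(names="probe_id")
        iomod._write_table(de_out, out / "de_screen.tsv", header("de-screen"))
        return de

    de = run_stage("de-screen", _screen)
    summary["de_flagged"] = int(de["flagged"].sum())

    # ---- bootstrap R-SVM selection ----------------------------------
    def _select():
        rsvm_cfg = dataclasses.replace(config.rsvm, seed=_stage_seed(config.seed, 1))
        sel = bootstrap_select(expr, labels, rsvm_cfg)
        table = sel.selection_count.reset_index()
        table.columns = ["probe_id", "selection_count"]
        table["in_signature"] = (table["selection_count"] >= 1).astype(int)
        iomod._write_table(table, out / "selection.tsv", header("select"))
        return sel

    selection = run_stage("select", _select)
    summary["n_selected_probes"] = len(selection.signature_probes)
    summary["cv_error_by_level"] = {
        str(k): round(v, 6) for k, v in sorted(selection.cv_error_by_level.items())
    }

    # ---- probe -> gene collapse and enrichment ----------------------
    selected_genes = run_stage(
        "map-genes", lambda: map_probes_to_genes(selection.signature_probes, annotation)
    )
    summary["n_selected_genes"] = len(selected_genes)

    def _enrich():
        rows = hypergeom_enrich(selected_genes, genesets)
        iomod._write_table(enrichment_table(rows), out / "enrichment.tsv", header("enrich"))
        return rows

    enrichment = run_stage("enrich", _enrich)
    if enrichment:
        summary["top_term"] = enrichment[0].term_id
        summary["top_term_pvalue"] = float(enrichment[0].pvalue)

    # ---- signature extraction ---------------------------------------
    def _signature():
        if config.signature_probes is not None:
            probes = list(config.signature_probes)
        else:
            members = set()
            for row in enrichment:
                if row.term_id == config.signature_term:
                    members = set(row.genes)
            ann = dict(zip(annotation["probe_id"], annotation["gene_symbol"]))
            by_gene: dict[str, str] = {}
            for probe in sorted(selection.signature_probes):
                gene = str(ann.get(probe, "") or "")
                if gene in members and gene not in by_gene:
                    by_gene[gene] = probe  # one designated probe per gene
            probes = sorted(by_gene.values())
        if not probes:
            raise ValidationError(
                f"no signature probes for term {config.signature_term!r}"
            )
        return probes

    signature_probes = run_stage("signature", _signature)
    summary["signature_probes"] = signature_probes

    # ---- classifier --------------------------------------------------
    def _classify():
        counts = below_median_counts(expr, signature_probes, mode=config.classifier_mode)
        roc = roc_analysis(counts, labels, positive_label=config.positive_label)
        cutoff = config.cutoff if config.cutoff is not None else roc.cutoff
        predicted = classify(counts, cutoff)
        table = meta[["sample_id", "label"]].copy()
        table["count"] = counts.to_numpy()
        table["predicted"] = np.where(
            predicted, config.positive_label, "predicted_negative"
        )
        iomod._write_table(table, out / "classifier.tsv", header("classify"))
        iomod._write_table(roc.table(), out / "roc.tsv", header("classify"))
        return counts, roc, float(cutoff), predicted

    counts, roc, cutoff, predicted = run_stage("classify", _classify)
    summary.update(
        {
            "auc": round(roc.auc, 6),
            "cutoff": cutoff,
            "sensitivity": round(roc.sensitivity, 6),
            "specificity": round(roc.specificity, 6),
        }
    )

    # ---- survival ----------------------------------------------------
    def _survival():
        strata = np.where(predicted, "predicted_metastatic", "predicted_nonrecurrent")
        if len(set(strata)) != 2:
            raise ValidationError("classifier produced a single stratum")
        times = meta["dfs_months"].to_numpy(dtype=float)
        events = meta["event"].to_numpy(dtype=int)
        curves = km_by_group(times, events, strata)
        for name, curve in curves.items():
            iomod._write_table(curve.table(), out / f"km_{name}.tsv", header("survival"))
        chi2, p = logrank_by_group(times, events, strata)
        return chi2, p

    chi2, p = run_stage("survival", _survival)
    summary["logrank_chi2"] = round(chi2, 6)
    summary["logrank_p"] = float(f"{p:.6g}")

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
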