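#!/usr/bin/env python
"""Optional workflow for the deposited array data (GEO accession GSE31905).

This script is NOT part of the automated test or acceptance runs: it
requires a locally downloaded series-matrix file (no download is
attempted here).  Given that file plus a sample-metadata TSV and a
probe annotation TSV, it runs the discovery pipeline on the real
cohort: bootstrap R-SVM selection, probe-to-gene collapse, GO
over-representation, the below-median-count classifier at the 8.5
cutoff, and the log-rank comparison of the predicted strata.

Usage:
    python scripts/gse31905_workflow.py \
        --series-matrix GSE31905_series_matrix.txt \
        --meta meta.tsv --annotation annotation.tsv --genesets go_bp.tsv \
        --out results/gse31905
"""

from __future__ import annotations

import argparse
from pathlib import Path

from immunosig import PipelineConfig, run_pipeline
from immunosig.io import read_series_matrix, write_expression, provenance_header


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--series-matrix", required=True, type=Path)
    parser.add_argument("--meta", required=True, type=Path)
    parser.add_argument("--annotation", required=True, type=Path)
    parser.add_argument("--genesets", required=True, type=Path)
    parser.add_argument("--out", required=True, type=Path)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--cutoff", type=float, default=8.5)
    args = parser.parse_args()

    args.out.mkdir(parents=True, exist_ok=True)
    expr = read_series_matrix(args.series_matrix)
    expr_path = args.out / "expression.tsv"
    write_expression(expr, expr_path, provenance_header("import", seed=args.seed))

    config = PipelineConfig(
        expression=str(expr_path),
        metadata=str(args.meta),
        annotation=str(args.annotation),
        genesets=str(args.genesets),
        out_dir=str(args.out / "run"),
        seed=args.seed,
        cutoff=args.cutoff,
    )
    summary = run_pipeline(config)
    print(
        f"selected probes: {summary['n_selected_probes']}; "
        f"AUC = {summary['auc']}; log-rank p = {summary['logrank_p']}"
    )


if __name__ == "__main__":
    main()
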