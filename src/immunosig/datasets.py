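"""Synthetic cohort and qPCR generators.

The generators emulate the statistical structure of an early-colorectal-
carcinoma expression study: 45 tumors (33 non-recurrent, 12 with later
metachronous metastasis) profiled on a ~44,000-probe array, in which a
14-gene immune signature is down-regulated in the metastatic group —
heterogeneously, so that in any one metastatic sample only a random
subset of the signature genes is shifted ("not always the same genes").
That heterogeneity is what defeats a univariate differential-expression
screen while leaving the signature recoverable multivariately.

Expression values are produced directly on the variance-stabilized
(log-like) scale the downstream analysis assumes: a broad per-probe
baseline plus i.i.d. Gaussian noise, with a per-sample Bernoulli subset
of signature probes shifted down by the effect size in metastatic
samples.  Follow-up is uniform over the study's observation window for
non-recurrent patients (censored) and log-normal with the study's
median disease-free survival for metastatic patients (all events).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .resources import IMMUNE_SIGNATURE_GENES, IMMUNE_SIGNATURE_PROBES

NONRECURRENT = "non_recurrent"
METASTATIC = "metastatic"

# log-normal sigma chosen so that median 13 months implies mean 17 months,
# matching the reported metastatic disease-free survival summaries
_DFS_MEAN_OVER_MEDIAN = 17.0 / 13.0


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the study conditions: 33 non-recurrent vs 12
    metastatic samples, ~44k probes, the 14 immune-signature genes
    planted with a moderate down-shift at incomplete penetrance, and
    the study's follow-up structure.
    """

    n_nonrecurrent: int = 33
    n_metastatic: int = 12
    n_probes: int = 44_000
    signature_genes: tuple[str, ...] = IMMUNE_SIGNATURE_GENES
    effect_size: float = 2.0  # mean down-shift delta, transformed units
    penetrance: float = 0.7  # P(a signature gene is shifted in a metastatic sample)
    noise_sd: float = 1.0  # within-group SD, transformed units
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    followup_range: tuple[float, float] = (41.0, 115.0)  # months, non-recurrent
    dfs_median_metastatic: float = 13.0  # months
    probes_per_signature_gene: int = 1
    annotation_rate: float = 0.7  # fraction of background probes with a gene symbol
    n_background_terms: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.n_nonrecurrent < 1 or self.n_metastatic < 1:
            raise ConfigError("n_nonrecurrent and n_metastatic must each be >= 1")
        if self.n_nonrecurrent + self.n_metastatic < 4:
            raise ConfigError("n_nonrecurrent + n_metastatic must be >= 4")
        if not self.signature_genes:
            raise ConfigError("signature_genes must be non-empty")
        if len(set(self.signature_genes)) != len(self.signature_genes):
            raise ConfigError("signature_genes must be unique")
        if self.n_probes < len(self.signature_genes) * self.probes_per_signature_gene:
            raise ConfigError("n_probes must be >= number of signature probes")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigError("penetrance must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        lo, hi = self.followup_range
        if not 0 < lo <= hi:
            raise ConfigError("followup_range must satisfy 0 < low <= high")
        if self.dfs_median_metastatic <= 0:
            raise ConfigError("dfs_median_metastatic must be > 0")
        if self.probes_per_signature_gene < 1:
            raise ConfigError("probes_per_signature_gene must be >= 1")
        if not 0.0 <= self.annotation_rate <= 1.0:
            raise ConfigError("annotation_rate must lie in [0, 1]")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticCohort:
    """A generated cohort: expression, metadata, annotations and truth."""

    expression: pd.DataFrame  # probes x samples, transformed scale
    metadata: pd.DataFrame  # sample_id, label, dfs_months, event
    probe_annotation: pd.DataFrame  # probe_id, gene_symbol ('' = none)
    geneset_annotation: dict[str, dict]  # term_id -> {"name", "genes": set}
    truth: frozenset[str] = field(default_factory=frozenset)  # planted probe ids
    config: CohortConfig | None = None


def _signature_probe_ids(config: CohortConfig) -> tuple[list[str], list[str]]:
    """Probe ids and matching gene symbols for the planted signature."""
    probes, genes = [], []
    for gene in config.signature_genes:
        base = IMMUNE_SIGNATURE_PROBES.get(gene, f"A_SIG_{gene}")
        for k in range(config.probes_per_signature_gene):
            probes.append(base if k == 0 else f"{base}_dup{k}")
            genes.append(gene)
    return probes, genes


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort under ``config``.

    Background probes are i.i.d. Gaussian around probe-specific baselines;
    each metastatic sample down-shifts an independent Bernoulli(penetrance)
    subset of the signature probes by ``effect_size``.
    """
    if config is None:
        config = CohortConfig()
    if overrides:
        config = config.replace(**overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)

    n0, n1 = config.n_nonrecurrent, config.n_metastatic
    n_samples = n0 + n1
    sig_probes, sig_genes = _signature_probe_ids(config)
    n_sig = len(sig_probes)
    n_bg = config.n_probes - n_sig

    probe_ids = sig_probes + [f"A_SYN_P{i:06d}" for i in range(n_bg)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    labels = np.array([NONRECURRENT] * n0 + [METASTATIC] * n1)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_probes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, (config.n_probes, n_samples)
    )
    # heterogeneous down-regulation: per metastatic sample, a random subset
    shift_mask = rng.random((n_sig, n1)) < config.penetrance
    values[:n_sig, n0:] -= config.effect_size * shift_mask

    expression = pd.DataFrame(values, index=probe_ids, columns=sample_ids)

    # survival: censored uniform follow-up vs log-normal event times
    lo, hi = config.followup_range
    t_nonrec = rng.uniform(lo, hi, n0)
    sigma = math.sqrt(2.0 * math.log(_DFS_MEAN_OVER_MEDIAN))
    t_met = rng.lognormal(math.log(config.dfs_median_metastatic), sigma, n1)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "label": labels,
            "dfs_months": np.round(np.concatenate([t_nonrec, t_met]), 2),
            "event": np.concatenate([np.zeros(n0, int), np.ones(n1, int)]),
        }
    )

    # probe annotation: signature probes keep their gene; a fraction of the
    # background carries a synthetic symbol, the rest are symbol-less
    bg_symbols = np.array([f"GENE{i:05d}" for i in range(n_bg)], dtype=object)
    bg_symbols[rng.random(n_bg) >= config.annotation_rate] = ""
    probe_annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_symbol": list(sig_genes) + list(bg_symbols),
        }
    )

    geneset_annotation = _generate_genesets(config, rng, bg_symbols)
    return SyntheticCohort(
        expression=expression,
        metadata=metadata,
        probe_annotation=probe_annotation,
        geneset_annotation=geneset_annotation,
        truth=frozenset(sig_probes),
        config=config,
    )


def _generate_genesets(
    config: CohortConfig, rng: np.random.Generator, bg_symbols: np.ndarray
) -> dict[str, dict]:
    """Gene sets: one immune term holding the signature plus random terms."""
    background = [s for s in bg_symbols if s]
    # immune term spans ~7% of the annotated background (864 of ~12k in the
    # emulated annotation), capped for small test cohorts
    immune_extra = min(len(background), max(5, round(0.07 * len(background))), 860)
    immune_members = set(config.signature_genes) | set(
        rng.choice(background, immune_extra, replace=False) if immune_extra else []
    )
    sets: dict[str, dict] = {
        "GO:0002376": {"name": "immune system process", "genes": immune_members}
    }
    for i in range(config.n_background_terms):
        if not background:
            break
        size = int(min(len(background), max(3, rng.lognormal(3.0, 1.0))))
        members = set(rng.choice(background, size, replace=False))
        sets[f"GO:SYN{i:04d}"] = {"name": f"synthetic process {i}", "genes": members}
    return sets


def generate_qpcr(
    n_per_group: int,
    genes: list[str],
    effect: float = 2.0,
    seed: int = 0,
    reference_gene: str = "ACTB",
    calibrator: str = "HT29",
    ct_sd: float = 0.5,
) -> pd.DataFrame:
    """Simulate a TaqMan Ct table for a two-group validation cohort.

    Returns long-format rows (sample_id, group, gene, ct) including the
    reference gene for every sample and a calibrator cell-line sample.
    The metastatic group's target Cts are shifted up by ``effect`` cycles
    (higher Ct = lower expression), leaving the reference gene untouched.
    """
    if n_per_group < 2:
        raise ConfigError("n_per_group must be >= 2")
    if not genes:
        raise ConfigError("genes must be non-empty")
    rng = np.random.default_rng(seed)
    gene_baseline = {g: rng.uniform(22.0, 27.0) for g in genes}
    ref_baseline = 18.0

    rows = []
    samples = [(f"N{i + 1:02d}", NONRECURRENT) for i in range(n_per_group)]
    samples += [(f"M{i + 1:02d}", METASTATIC) for i in range(n_per_group)]
    for sid, group in samples:
        shift = effect if group == METASTATIC else 0.0
        rows.append((sid, group, reference_gene, ref_baseline + rng.normal(0, 0.3)))
        for g in genes:
            rows.append((sid, group, g, gene_baseline[g] + shift + rng.normal(0, ct_sd)))
    rows.append((calibrator, "calibrator", reference_gene, ref_baseline + rng.normal(0, 0.3)))
    for g in genes:
        rows.append((calibrator, "calibrator", g, gene_baseline[g] + rng.normal(0, ct_sd)))

    table = pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
    table["ct"] = table["ct"].round(4)
    return table


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict[str, str]:
    """Write a cohort's TSV files (expression, metadata, annotation, gene sets).

    Returns the paths keyed by pipeline-config field name.
    """
    from pathlib import Path

    from . import io as iomod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cohort.config.seed if cohort.config is not None else None
    head = iomod.provenance_header("simulate", seed=seed)
    paths = {
        "expression": str(out / "expression.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "annotation": str(out / "annotation.tsv"),
        "genesets": str(out / "genesets.tsv"),
    }
    iomod.write_expression(cohort.expression, paths["expression"], head)
    iomod.write_metadata(cohort.metadata, paths["metadata"], head)
    iomod.write_annotation(cohort.probe_annotation, paths["annotation"], head)
    iomod.write_genesets(cohort.geneset_annotation, paths["genesets"], head)
    return paths
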