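"""Relative quantification of qPCR data by the ΔΔCt method.

For each sample i and target gene g: ΔCt_i = Ct_i(g) - Ct_i(reference),
ΔΔCt_i = ΔCt_i - ΔCt_calibrator, and the relative expression is
RQ_i = 2^(-ΔΔCt_i), assuming 100% amplification efficiency (a factor
of exactly 2 per cycle).  The default reference gene is beta-actin
(ACTB) and the default calibrator the HT29 colorectal carcinoma cell
line.  Group differences in RQ are compared with the Mann-Whitney
test: exact by full enumeration for combined n <= 20, normal
approximation with tie correction otherwise.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .errors import ValidationError

EXACT_LIMIT = 20  # combined sample size up to which the exact test is used


def delta_delta_ct(
    table: pd.DataFrame,
    gene: str,
    reference_gene: str = "ACTB",
    calibrator: str = "HT29",
) -> pd.DataFrame:
    """Per-sample relative expression of ``gene`` by ΔΔCt.

    ``table`` is long-format with columns (sample_id, group, gene, ct);
    every sample must carry the reference gene and the calibrator
    sample must carry both the target and the reference.
    Returns a frame (sample_id, group, delta_ct, delta_delta_ct, rq)
    excluding the calibrator row.
    """
    required = {"sample_id", "group", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValidationError(f"Ct table must have columns {sorted(required)}")
    dup = table.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        pair = table.loc[dup, ["sample_id", "gene"]].iloc[0].tolist()
        raise ValidationError(f"duplicate (sample, gene) Ct entry: {pair}")

    ct = table.set_index(["sample_id", "gene"])["ct"]

    def _lookup(sample: str, g: str) -> float:
        try:
            return float(ct.loc[(sample, g)])
        except KeyError:
            raise ValidationError(f"missing Ct for sample {sample!r}, gene {g!r}")

    cal_dct = _lookup(calibrator, gene) - _lookup(calibrator, reference_gene)
    rows = []
    for sample, group in (
        table[table["sample_id"] != calibrator][["sample_id", "group"]]
        .drop_duplicates()
        .itertuples(index=False)
    ):
        dct = _lookup(sample, gene) - _lookup(sample, reference_gene)
        ddct = dct - cal_dct
        rows.append((sample, group, dct, ddct, 2.0 ** (-ddct)))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "delta_ct", "delta_delta_ct", "rq"]
    )


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (for group A) and two-sided p.

    Midranks handle ties.  For combined n <= 20 the p-value is exact:
    all C(n, n_a) assignments of the pooled values to group A are
    enumerated and assignments at least as extreme as observed (in
    |U - n_a n_b / 2|) are counted.  Larger samples use the normal
    approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n_b = a.size, b.size
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0

    if n_a + n_b <= EXACT_LIMIT:
        mu = n_a * n_b / 2.0
        dev_obs = abs(u_obs - mu) - 1e-12
        hits = total = 0
        base = n_a * (n_a + 1) / 2.0
        for idx in combinations(range(n_a + n_b), n_a):
            u = ranks[list(idx)].sum() - base
            total += 1
            if abs(u - mu) >= dev_obs:
                hits += 1
        return float(u_obs), hits / total

    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    rq: pd.DataFrame,
    group_a: str = "non_recurrent",
    group_b: str = "metastatic",
) -> dict:
    """Summarize one gene's RQ values by group with a Mann-Whitney test."""
    a = rq.loc[rq["group"] == group_a, "rq"].to_numpy()
    b = rq.loc[rq["group"] == group_b, "rq"].to_numpy()
    u, p = mann_whitney(a, b)
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "u": u,
        "pvalue": p,
    }
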