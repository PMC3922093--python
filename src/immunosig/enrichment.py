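"""Gene-set over-representation by the unconditional hypergeometric test.

For a selection of n genes out of a universe of N, a term annotated to
K universe genes, and an observed overlap a, the over-representation
p-value is the upper hypergeometric tail P(X >= a), the expected
overlap n*K/N, and the odds ratio the cross-product (a*d)/(b*c) of the
2x2 membership table (b = n-a, c = K-a, d = N-K-b).

Published over-representation tables often print (expected, odds
ratio, count, size) but omit the selection and universe sizes;
:func:`reconstruct_table_params` recovers the unique integer pair
(n, N) consistent with the printed 2-decimal values by grid search, so
printed p-values can be recomputed and audited exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ReconstructionError, ValidationError


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    a: int  # overlap count
    K: int  # term size in the universe
    n: int  # selection size
    N: int  # universe size
    expected: float
    odds_ratio: float
    pvalue: float
    genes: tuple[str, ...] = ()


def hypergeom_pvalue(a: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= a) for X ~ Hypergeom(N, K, n)."""
    if not 0 <= a <= min(n, K) or K > N or n > N:
        raise ValidationError("inconsistent 2x2 table: need 0 <= a <= min(n, K) <= N")
    return float(hypergeom.sf(a - 1, N, K, n))


def odds_ratio(a: int, K: int, n: int, N: int) -> float:
    """Sample odds ratio of the 2x2 membership table; inf when b*c = 0."""
    b, c = n - a, K - a
    d = N - K - b
    if min(b, c, d) < 0:
        raise ValidationError("inconsistent 2x2 table: negative cell")
    if b * c == 0:
        return float("inf")
    return (a * d) / (b * c)


def hypergeom_enrich(selected, universe_sets: dict[str, dict]) -> list[EnrichmentRow]:
    """Test every term for over-representation of ``selected`` genes.

    ``universe_sets`` maps term_id -> {"name": str, "genes": set}; the
    gene universe is the union of all term members (genes carrying at
    least one annotation).  Selected genes outside the universe are
    dropped with a warning.  Rows with zero overlap are omitted (their
    p is identically 1); output is sorted by ascending p-value.
    """
    universe: set[str] = set()
    for term in universe_sets.values():
        universe |= set(term["genes"])
    if not universe:
        raise ValidationError("empty gene universe")
    selected = list(dict.fromkeys(selected))  # dedupe, keep order
    effective = [g for g in selected if g in universe]
    if len(effective) < len(selected):
        warnings.warn(
            f"{len(selected) - len(effective)} selected gene(s) outside the "
            "annotation universe were dropped",
            RuntimeWarning,
            stacklevel=2,
        )
    if not effective:
        raise ValidationError("no selected gene lies in the annotation universe")

    N, n = len(universe), len(effective)
    sel = set(effective)
    rows = []
    for term_id, term in universe_sets.items():
        members = set(term["genes"]) & universe
        K = len(members)
        overlap = sorted(sel & members)
        a = len(overlap)
        if K == 0 or a == 0:
            continue
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                term_name=term.get("name", ""),
                a=a,
                K=K,
                n=n,
                N=N,
                expected=n * K / N,
                odds_ratio=odds_ratio(a, K, n, N),
                pvalue=hypergeom_pvalue(a, K, n, N),
                genes=tuple(overlap),
            )
        )
    rows.sort(key=lambda r: (r.pvalue, r.term_id))
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Tabulate enrichment rows in the published column layout."""
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "pvalue": [r.pvalue for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "expected": [r.expected for r in rows],
            "count": [r.a for r in rows],
            "size": [r.K for r in rows],
            "term_name": [r.term_name for r in rows],
            "genes": [";".join(r.genes) for r in rows],
        }
    )


def reconstruct_table_params(
    rows,
    n_range: tuple[int, int] = (None, 100),  # type: ignore[assignment]
    N_range: tuple[int, int] = (1000, 50000),
    decimals: int = 2,
) -> tuple[int, int]:
    """Recover (selection size n, universe size N) from printed table rows.

    ``rows`` is an iterable of (expected, odds_ratio, a, K) tuples as
    printed (rounded to ``decimals``).  A grid search over integer
    n and N returns the pair for which every row's recomputed expected
    value and odds ratio round to the printed numbers.  Raises
    :class:`ReconstructionError` when no pair, or more than one pair,
    is consistent (ambiguous input).
    """
    rows = [(float(e), float(o), int(a), int(K)) for e, o, a, K in rows]
    if not rows:
        raise ValidationError("at least one printed row is required")
    a_max = max(a for _, _, a, _ in rows)
    n_lo = a_max if n_range[0] is None else max(n_range[0], a_max)
    n_hi = n_range[1]
    N_lo, N_hi = N_range
    tol = 0.5 * 10.0 ** (-decimals) + 1e-12

    N_grid = np.arange(N_lo, N_hi + 1, dtype=float)
    candidates: list[tuple[int, int]] = []
    for n in range(n_lo, n_hi + 1):
        ok = np.ones(N_grid.size, dtype=bool)
        for expected, orr, a, K in rows:
            if a > min(n, K):
                ok[:] = False
                break
            b, c = n - a, K - a
            d = N_grid - K - b
            ok &= d >= 0
            ok &= np.abs(n * K / N_grid - expected) <= tol
            if b * c == 0:
                ok &= np.isinf(orr)
            else:
                ok &= np.abs((a * d) / (b * c) - orr) <= tol
            if not ok.any():
                break
        for N in N_grid[ok]:
            candidates.append((n, int(N)))
    if not candidates:
        raise ReconstructionError(
            "no (n, N) pair in the search ranges is consistent with the printed rows"
        )
    if len(candidates) > 1:
        shown = ", ".join(map(str, candidates[:10]))
        raise ReconstructionError(
            f"ambiguous reconstruction: {len(candidates)} consistent pairs ({shown}...)"
        )
    return candidates[0]


def map_probes_to_genes(probes, annotation) -> list[str]:
    """Collapse probe ids to unique, non-empty gene symbols (stable order).

    ``annotation`` maps probe id -> gene symbol; probes without a symbol
    (missing, empty, or NaN) are dropped, and duplicate symbols are
    collapsed to their first occurrence.
    """
    if isinstance(annotation, pd.DataFrame):
        annotation = dict(
            zip(annotation["probe_id"], annotation["gene_symbol"].fillna(""))
        )
    seen: dict[str, None] = {}
    for probe in probes:
        symbol = annotation.get(probe, "")
        if symbol is None or (isinstance(symbol, float) and np.isnan(symbol)):
            continue
        symbol = str(symbol).strip()
        if symbol:
            seen.setdefault(symbol, None)
    return list(seen)
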