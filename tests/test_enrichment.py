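"""Hypergeometric over-representation and printed-table reconstruction."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest

import immunosig as im
from immunosig.resources import GO_ENRICHMENT_ANCHORS, SIGNATURE_PROBE_ANNOTATION


def upper_tail_by_enumeration(a, K, n, N):
    """Exhaustive draw of every size-n selection from an N-gene universe."""
    universe = range(N)
    term = set(range(K))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        hits += len(term.intersection(draw)) >= a
    return Fraction(hits, total)


def upper_tail_closed_form(a, K, n, N):
    """Exact rational sum of the hypergeometric upper tail."""
    num = sum(comb(K, k) * comb(N - K, n - k) for k in range(a, min(n, K) + 1))
    return Fraction(num, comb(N, n))


class TestHypergeomPvalue:
    def test_hand_example_matches_exhaustive_draw(self):
        # N=10, K=4, n=3, a=2 -> (C(4,2)C(6,1)+C(4,3)C(6,0))/C(10,3) = 40/120
        exact = upper_tail_by_enumeration(2, 4, 3, 10)
        assert exact == Fraction(1, 3)
        assert im.hypergeom_pvalue(2, 4, 3, 10) == pytest.approx(float(exact))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_rational_tail_for_small_universes(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 61))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        a = int(rng.integers(0, min(n, K) + 1))
        expected = float(upper_tail_closed_form(max(a, 1), K, n, N))
        assert im.hypergeom_pvalue(max(a, 1), K, n, N) == pytest.approx(
            expected, rel=1e-12
        )

    def test_p_nonincreasing_in_overlap(self):
        ps = [im.hypergeom_pvalue(a, 20, 15, 100) for a in range(1, 16)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_odds_ratio_saturation_is_infinite_not_nan(self):
        assert im.enrichment.odds_ratio(3, 3, 5, 50) == float("inf")
        assert im.enrichment.odds_ratio(5, 8, 5, 50) == float("inf")


class TestHypergeomEnrich:
    @staticmethod
    def _published_scale_universe():
        genes = [f"g{i}" for i in range(12_464)]
        return {
            "GO:TEST": {"name": "mhc class II presentation", "genes": set(genes[:18])},
            "GO:ALL": {"name": "background", "genes": set(genes)},
        }

    def test_reproduces_published_row_statistics(self):
        sets = self._published_scale_universe()
        selected = [f"g{i}" for i in range(4)] + [f"g{i}" for i in range(100, 117)]
        rows = im.hypergeom_enrich(selected, sets)
        row = next(r for r in rows if r.term_id == "GO:TEST")
        assert (row.a, row.K, row.n, row.N) == (4, 18, 21, 12_464)
        assert row.pvalue == pytest.approx(1.8e-08, rel=0.05)
        assert row.odds_ratio == pytest.approx(208.89, abs=0.005)
        assert row.expected == pytest.approx(0.03, abs=0.005)

    def test_zero_overlap_rows_omitted(self):
        sets = {
            "GO:A": {"name": "", "genes": {"x", "y"}},
            "GO:B": {"name": "", "genes": {"z", "w"}},
        }
        rows = im.hypergeom_enrich(["x"], sets)
        assert [r.term_id for r in rows] == ["GO:A"]

    def test_out_of_universe_selection_dropped_with_warning(self):
        sets = {"GO:A": {"name": "", "genes": {"x", "y", "z"}}}
        with pytest.warns(RuntimeWarning, match="outside"):
            rows = im.hypergeom_enrich(["x", "nope"], sets)
        assert rows[0].n == 1
        with pytest.raises(im.ValidationError):
            im.hypergeom_enrich(["nope"], sets)

    def test_random_selection_not_overdetected(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(200)]
        sets = {
            f"GO:{t}": {"name": "", "genes": set(rng.choice(genes, 20, replace=False))}
            for t in range(10)
        }
        sets["GO:ALL"] = {"name": "", "genes": set(genes)}
        alpha = 0.1
        hits = {t: 0 for t in sets}
        n_runs = 200
        for _ in range(n_runs):
            selected = list(rng.choice(genes, 20, replace=False))
            rows = {r.term_id: r for r in im.hypergeom_enrich(selected, sets)}
            for t in hits:
                if t in rows and rows[t].pvalue < alpha:
                    hits[t] += 1
        for t, h in hits.items():
            if t != "GO:ALL":
                assert h / n_runs <= alpha * 1.6 + 0.02


class TestReconstruction:
    @staticmethod
    def _anchor_rows(term_ids):
        by_id = {r["term_id"]: r for r in GO_ENRICHMENT_ANCHORS}
        return [
            (by_id[t]["expected"], by_id[t]["odds_ratio"], by_id[t]["count"], by_id[t]["size"])
            for t in term_ids
        ]

    def test_published_anchor_rows_pin_unique_pair(self):
        rows = self._anchor_rows(["GO:0002376", "GO:0006955", "GO:0019882"])
        assert im.reconstruct_table_params(rows) == (21, 12_464)
        rows2 = self._anchor_rows(["GO:0002376", "GO:0006955", "GO:0002504"])
        assert im.reconstruct_table_params(rows2) == (21, 12_464)

    def test_unrounded_rows_round_trip_exactly(self):
        n, N = 25, 2000
        rows = []
        for K, a in ((50, 5), (120, 10), (400, 3)):
            rows.append((n * K / N, im.enrichment.odds_ratio(a, K, n, N), a, K))
        assert im.reconstruct_table_params(rows, decimals=6) == (n, N)

    def test_single_row_is_ambiguous(self):
        rows = self._anchor_rows(["GO:0002376"])
        with pytest.raises(im.ReconstructionError, match="ambiguous"):
            im.reconstruct_table_params(rows)

    def test_inconsistent_rows_fail(self):
        with pytest.raises(im.ReconstructionError, match="no .* pair"):
            im.reconstruct_table_params([(9.99, 1.23, 2, 10), (0.01, 99.0, 3, 500)])


class TestProbeGeneCollapse:
    def test_symbol_less_probe_dropped(self):
        ann = {"p1": "A", "p2": "", "p3": "B"}
        assert im.map_probes_to_genes(["p1", "p2", "p3"], ann) == ["A", "B"]

    def test_duplicate_symbols_collapse(self):
        ann = {"p1": "A", "p2": "A"}
        assert im.map_probes_to_genes(["p1", "p2"], ann) == ["A"]

    def test_published_signature_table_collapse(self):
        ann = dict(SIGNATURE_PROBE_ANNOTATION)
        probes = [p for p, _ in SIGNATURE_PROBE_ANNOTATION]
        assert len(probes) == 44
        with_symbol = [p for p, s in SIGNATURE_PROBE_ANNOTATION if s]
        assert len(with_symbol) == 30
        symbols = im.map_probes_to_genes(probes, ann)
        # 30 symbol-bearing probes collapse to 25 genes (IGHG1 x4, PCSK1 x2, PIGR x2)
        assert len(symbols) == 25
        assert set(im.resources.IMMUNE_SIGNATURE_GENES) <= set(symbols)
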