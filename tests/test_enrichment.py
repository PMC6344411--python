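"""Fisher exact test, BH control, Simpson coefficients, network assembly."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from nicodh import (
    ContextScenario, ContingencyTable, bh_adjust, build_feature_matrix,
    build_network, fisher_exact_greater, generate_context_genomes,
    simpson_coefficient,
)
from nicodh.context import ContextLocus
from nicodh.enrichment import find_enriched_cogs
from nicodh.context import genes_from_dataframe

import oracles


class TestFisherExactGreater:
    def test_fully_concentrated_table(self):
        # margins (5,5;5): P(X >= 5) = 1/C(10,5) = 1/252
        p = fisher_exact_greater(ContingencyTable(5, 0, 0, 5))
        assert p == pytest.approx(1 / 252, abs=1e-15)

    def test_zero_successes_gives_one(self):
        assert fisher_exact_greater(ContingencyTable(0, 7, 3, 11)) == 1.0

    def test_zero_margin_gives_one(self):
        assert fisher_exact_greater(ContingencyTable(0, 0, 5, 5)) == 1.0
        assert fisher_exact_greater(ContingencyTable(0, 5, 0, 5)) == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = random.Random(17)
        for _ in range(500):
            a, b, c, d = (rng.randrange(0, 11) for _ in range(4))
            p = fisher_exact_greater(ContingencyTable(a, b, c, d))
            assert p == pytest.approx(
                oracles.fisher_greater_enumeration(a, b, c, d), abs=1e-12
            )

    def test_matches_scipy_one_sided(self):
        rng = random.Random(23)
        for _ in range(100):
            a, b, c, d = (rng.randrange(0, 15) for _ in range(4))
            ours = fisher_exact_greater(ContingencyTable(a, b, c, d))
            _, ref = scipy.stats.fisher_exact([[a, b], [c, d]],
                                              alternative="greater")
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestBHAdjust:
    def test_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == \
            pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_matches_direct_formula(self):
        rng = random.Random(29)
        ps = [rng.random() for _ in range(50)]
        assert bh_adjust(ps) == pytest.approx(oracles.bh_stepup(ps))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_q_between_p_and_one_and_permutation_equivariant(self, ps):
        qs = bh_adjust(ps)
        for p, q in zip(ps, qs):
            assert p - 1e-12 <= q <= 1.0
        perm = list(range(len(ps)))
        random.Random(0).shuffle(perm)
        qs_perm = bh_adjust([ps[i] for i in perm])
        assert qs_perm == pytest.approx([qs[i] for i in perm])

    def test_sorted_inputs_yield_nondecreasing_q(self):
        qs = bh_adjust(sorted([0.001, 0.2, 0.04, 0.9, 0.5]))
        assert qs == sorted(qs)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestSimpsonCoefficient:
    def test_identical_sets(self):
        assert simpson_coefficient({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_subset_scores_one(self):
        assert simpson_coefficient({1, 2}, {1, 2, 3, 4}) == 1.0

    def test_partial_overlap(self):
        u = {1, 2, 3, 4}
        v = {3, 4, *range(10, 18)}
        assert simpson_coefficient(u, v) == 0.5

    def test_symmetric_and_zero_iff_disjoint(self):
        rng = random.Random(41)
        for _ in range(50):
            u = set(rng.sample(range(30), rng.randrange(1, 10)))
            v = set(rng.sample(range(30), rng.randrange(1, 10)))
            s = simpson_coefficient(u, v)
            assert s == simpson_coefficient(v, u)
            assert 0.0 <= s <= 1.0
            assert (s == 0.0) == (not u & v)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            simpson_coefficient(set(), {1})


def _matrix(columns: dict[str, set[str]]) -> pd.DataFrame:
    loci = sorted(set().union(*columns.values()))
    return pd.DataFrame(
        {col: [l in members for l in loci] for col, members in columns.items()},
        index=loci, dtype=bool,
    )


class TestBuildNetwork:
    def test_edge_threshold_boundary(self):
        loci = [f"l{i:03d}" for i in range(100)]
        # overlap 20 over min size 50 -> exactly 0.40: edge emitted
        mat40 = _matrix({"SG:A": set(loci[:50]), "SG:B": set(loci[30:80])})
        edges = build_network(mat40, tau=0.4)
        assert [(e.u, e.v, e.simpson) for e in edges] == \
            [("SG:A", "SG:B", pytest.approx(0.40))]
        # overlap 39 over min size 100 -> 0.39: no edge
        big = [f"m{i:03d}" for i in range(200)]
        mat39 = _matrix({
            "SG:U": set(big[:100]),
            "SG:V": set(big[61:161]),
        })
        assert build_network(mat39, tau=0.4) == []

    def test_cog_locus_floor_applies_to_cogs_only(self):
        loci = [f"l{i}" for i in range(30)]
        mat = _matrix({
            "COG:COG0001": set(loci[:24]),   # below the 25-locus floor
            "COG:COG0002": set(loci[:25]),
            "SG:F-1": set(loci[:3]),         # groups are exempt
            "FAM:Family01": set(loci[:3]),
        })
        edges = build_network(mat, tau=0.4)
        nodes = {e.u for e in edges} | {e.v for e in edges}
        assert "COG:COG0001" not in nodes
        assert {"COG:COG0002", "SG:F-1", "FAM:Family01"} <= nodes

    def test_feature_matrix_rows_nonempty_and_namespaced(self):
        loci = [
            ContextLocus("p1", "g1", ["p1"], [], frozenset({"COGE", "COGB"}),
                         group_label="F-1", family="Family01"),
            ContextLocus("p2", "g2", ["p2"], [], frozenset(),
                         group_label="C-2", family="Family02"),
        ]
        mat = build_feature_matrix(loci, {"COGE"})
        assert set(mat.columns) == {"COG:COGE", "SG:F-1", "SG:C-2",
                                    "FAM:Family01", "FAM:Family02"}
        assert mat.loc["p1", "COG:COGE"]
        assert "COG:COGB" not in mat.columns  # only enriched COGs become features
        assert mat.sum(axis=1).min() >= 1


class TestFindEnrichedCogs:
    @staticmethod
    def _run(scenario):
        bundle = generate_context_genomes(scenario)
        genes_by_rep = genes_from_dataframe(bundle.genes)
        from nicodh import build_all_directons, build_context_loci

        directons = build_all_directons(genes_by_rep)
        annotations = {}
        for r in bundle.annotations.itertuples():
            annotations.setdefault(r.protein_id, set()).add(r.cog)
        loci = build_context_loci(genes_by_rep, directons, set(), annotations)
        return find_enriched_cogs(loci, genes_by_rep, annotations)

    def test_fully_planted_cog_is_enriched(self):
        scen = ContextScenario(n_genomes=20, genes_per_replicon=40,
                               enriched_cogs=(("COGX", 1.0),),
                               background_cogs=(("COGB", 0.02),), seed=13)
        enriched, results = self._run(scen)
        assert "COGX" in enriched
        rx = next(r for r in results if r.cog == "COGX")
        assert rx.table.a == 20 and rx.table.c == 0
        assert rx.p < 1e-10 and rx.q < 1e-8

    def test_codh_marker_cogs_never_flagged(self):
        scen = ContextScenario(n_genomes=20, genes_per_replicon=40,
                               enriched_cogs=(("COGX", 1.0),),
                               background_cogs=(), seed=13)
        enriched, results = self._run(scen)
        # COG1151 marks the CODH genes themselves: maximally enriched, excluded
        assert "COG1151" not in enriched
        assert all(r.cog != "COG1151" for r in results)

    def test_uniform_background_cog_rarely_flagged(self):
        flagged = 0
        n_sim = 25
        for i in range(n_sim):
            scen = ContextScenario(n_genomes=15, genes_per_replicon=40,
                                   enriched_cogs=(),
                                   background_cogs=(("COGB", 0.02),),
                                   seed=500 + i)
            enriched, _ = self._run(scen)
            flagged += "COGB" in enriched
        assert flagged <= max(1, 0.05 * n_sim)
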