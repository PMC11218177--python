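"""Germline filter cascade, CGC screen, category comparison, enrichment."""

from math import comb

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from multifoci.errors import InputDataError
from multifoci.germline import (
    compare_category,
    enrich_sets,
    filter_germline,
    intersect_cgc,
)
from _oracles import hypergeom_permutation_oracle
from conftest import make_variant


def _gv(**kw):
    base = dict(variant_class="germline", gene="TP53", region="exonic",
                consequence="nonsynonymous", depth=50)
    base.update(kw)
    return make_variant(**base)


class TestFilterCascade:
    def test_cosmic_rescue_retains_common_cancer_variant(self):
        v = _gv(af_1kg=0.005, cosmic_flag=True)
        profile = filter_germline([v])
        assert profile.retained == [v]

    def test_depth_rule_drops_first(self):
        v = _gv(depth=9, af_1kg=0.5, region="intronic", repeat_flag=True)
        profile = filter_germline([v])
        assert profile.drop_counts["depth"] == 1 and not profile.retained

    @pytest.mark.parametrize(
        "kw,rule",
        [
            ({"af_1kg": 0.005}, "population_af"),
            ({"af_exac": 0.5}, "population_af"),
            ({"region": "intronic", "af_1kg": 1e-5}, "region"),
            ({"region": "intergenic"}, "region"),
            ({"region": "ncRNA"}, "region"),
            ({"region": "UTR"}, "region"),
            ({"consequence": "synonymous"}, "region"),
            ({"repeat_flag": True}, "repeat"),
            ({"depth": None}, "no_depth"),
        ],
    )
    def test_drop_attribution(self, kw, rule):
        profile = filter_germline([_gv(**kw)])
        assert profile.drop_counts[rule] == 1
        assert sum(profile.drop_counts.values()) == 1

    def test_af_boundary_inclusive(self):
        # "greater than 0.001 filtered out": exactly 0.001 is retained
        assert filter_germline([_gv(af_1kg=0.001)]).retained
        assert not filter_germline([_gv(af_1kg=0.0011)]).retained

    def test_missing_af_treated_as_novel(self):
        assert filter_germline([_gv()]).retained

    def test_partition_identity(self):
        variants = [_gv(), _gv(depth=5), _gv(af_1kg=0.3), _gv(region="intronic"),
                    _gv(repeat_flag=True), _gv(depth=None)]
        p = filter_germline(variants)
        assert p.n_input == len(variants)
        assert len(p.retained) + sum(p.drop_counts.values()) == len(variants)

    def test_idempotence(self):
        variants = [_gv(), _gv(af_1kg=0.3), _gv(depth=3), _gv(cosmic_flag=True, af_exac=0.02)]
        once = filter_germline(variants).retained
        twice = filter_germline(once).retained
        assert twice == once

    @settings(max_examples=100, derandomize=True)
    @given(
        depth=st.one_of(st.none(), st.integers(0, 60)),
        af=st.one_of(st.none(), st.floats(0, 0.5)),
        cosmic=st.booleans(),
        region=st.sampled_from(["exonic", "splicing", "intronic", "UTR", "ncRNA", "intergenic"]),
        csq=st.sampled_from(["nonsynonymous", "synonymous", "stopgain", "frameshift"]),
        repeat=st.booleans(),
    )
    def test_retention_is_a_pure_conjunction(self, depth, af, cosmic, region, csq, repeat):
        """Rules (ii)-(iv) commute: retention equals the conjunction of the
        individual rules regardless of evaluation order."""
        v = _gv(depth=depth, af_1kg=af, cosmic_flag=cosmic, region=region,
                consequence=csq, repeat_flag=repeat)
        retained = bool(filter_germline([v]).retained)
        expected = (
            depth is not None and depth >= 10
            and (cosmic or (af or 0.0) <= 0.001)
            and region in ("exonic", "splicing") and csq != "synonymous"
            and not repeat
        )
        assert retained == expected

    def test_monotone_in_af_threshold(self):
        variants = [_gv(af_1kg=a) for a in (0.0, 1e-4, 5e-4, 1e-3, 5e-3, 0.05)]
        sizes = [
            len(filter_germline(variants, af_threshold=t).retained)
            for t in (0.05, 0.01, 0.001, 1e-4, 0.0)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestCgcIntersection:
    def test_intersection_and_dedup(self):
        profile = filter_germline([_gv(gene="TP53"), _gv(pos=222, gene="TP53"),
                                   _gv(pos=333, gene="OR2T4")])
        assert intersect_cgc(profile, ["TP53", "BRCA2"]) == ["TP53"]

    def test_no_overlap_and_empty_cgc(self):
        profile = filter_germline([_gv(gene="OR2T4")])
        assert intersect_cgc(profile, ["TP53"]) == []
        assert intersect_cgc(profile, []) == []


class TestCompareCategory:
    def _profiles(self, counts, category="immune"):
        out = []
        for i, c in enumerate(counts):
            variants = [_gv(pos=100 + j, gene="HLA-A") for j in range(c)]
            cats = pd.DataFrame({"gene": ["HLA-A"], "category": [category]})
            out.append(filter_germline(variants, f"P{i}", cats))
        return out

    def test_complete_separation(self):
        mc = self._profiles([8, 9, 10, 11, 12, 13])
        me = self._profiles([1, 2, 3, 4])
        p, mc_counts, me_counts = compare_category(mc, me, "immune")
        assert mc_counts == [8, 9, 10, 11, 12, 13] and me_counts == [1, 2, 3, 4]
        assert p == pytest.approx(2 / 210)

    def test_identical_distributions(self):
        p, *_ = compare_category(self._profiles([5, 5]), self._profiles([5, 5]), "immune")
        assert p == 1.0

    def test_total_category(self):
        p, mc, me = compare_category(self._profiles([3, 4]), self._profiles([4, 3]), "total")
        assert sorted(mc) == sorted(me) and p == 1.0


class TestEnrichment:
    def test_closed_form_hypergeometric(self):
        universe = [f"G{i}" for i in range(100)]
        annotation = pd.DataFrame({"gene": [f"G{i}" for i in range(10)], "set": "S"})
        query = [f"G{i}" for i in range(5)]  # all 5 in the 10-gene set
        out = enrich_sets(query, annotation, universe)
        expected = comb(10, 5) * comb(90, 0) / comb(100, 5)
        assert out.loc[0, "p_value"] == pytest.approx(expected, rel=1e-12)

    def test_query_equals_universe(self):
        universe = [f"G{i}" for i in range(8)]
        annotation = pd.DataFrame({"gene": universe[:4], "set": "S"})
        out = enrich_sets(universe, annotation, universe)
        assert (out["p_value"] == 1.0).all()

    def test_bh_adjustment_by_hand(self):
        universe = [f"G{i}" for i in range(40)]
        # three disjoint sets with different overlaps -> distinct raw ps
        ann = pd.DataFrame(
            {"gene": universe[:6] + universe[6:12] + universe[12:18],
             "set": ["A"] * 6 + ["B"] * 6 + ["C"] * 6}
        )
        query = universe[:5] + universe[6:9] + universe[12:13]
        out = enrich_sets(query, ann, universe).set_index("set")
        raw = out["p_value"]
        expected = {}
        order = raw.sort_values().index
        prev = 1.0
        for rank, name in list(enumerate(order, start=1))[::-1]:
            val = min(prev, raw[name] * 3 / rank)
            expected[name] = val
            prev = val
        for name in order:
            assert out.loc[name, "p_adjusted"] == pytest.approx(expected[name], rel=1e-12)

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(InputDataError, match="not in universe"):
            enrich_sets(["X"], pd.DataFrame({"gene": ["A"], "set": ["S"]}), ["A"])

    def test_matches_permutation_oracle(self):
        M, K, N, k = 60, 12, 8, 4
        p_exact = float(hypergeom.sf(k - 1, M, K, N))
        p_mc, se = hypergeom_permutation_oracle(M, K, N, k, n_draws=10_000, seed=5)
        assert abs(p_exact - p_mc) <= 3 * se
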