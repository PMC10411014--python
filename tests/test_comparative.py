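"""Set summaries, rank correlation, and KEGG module boolean semantics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pancore import comparative
from pancore.ancestral import AncestralProfile


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [({"x", "y"}, {"x", "y"}, 1.0), ({"x"}, {"y"}, 0.0), ({"a", "b"}, {"b", "c"}, 1 / 3)],
    )
    def test_values(self, a, b, expected):
        assert comparative.jaccard(a, b) == pytest.approx(expected)

    def test_two_empty_sets_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert comparative.jaccard(set(), set()) == 0.0


class TestCategoryDistribution:
    def test_simple_fractions(self):
        dist = comparative.category_distribution(
            ["g1", "g2", "g3", "g4"], {"g1": "J", "g2": "J", "g3": "E", "g4": "S"})
        assert dist == {"J": 0.5, "E": 0.25, "S": 0.25}

    def test_multi_letter_split(self):
        dist = comparative.category_distribution(["g1"], {"g1": "EK"})
        assert dist == {"E": 0.5, "K": 0.5}

    def test_unannotated_maps_to_S(self):
        dist = comparative.category_distribution(["g1", "g2"], {"g1": "J"})
        assert dist["S"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        letters = "JEKCPMS"
        genes = [f"g{i}" for i in range(200)]
        ann = {
            g: "".join(rng.choice(list(letters), size=rng.integers(1, 4), replace=False))
            for g in genes if rng.random() > 0.1
        }
        dist = comparative.category_distribution(genes, ann)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


class TestThresholdPrevalenceCorrelation:
    def _prof(self, og, min_g, prev):
        return AncestralProfile(og, (min_g,) if min_g is not None else (), min_g, prev)

    def test_perfect_anticoncordance(self):
        profiles = [self._prof(f"og{i}", 2.0 - 0.1 * i, 0.1 * i) for i in range(5)]
        res = comparative.threshold_prevalence_correlation(profiles)
        assert res.rho == pytest.approx(-1.0)

    def test_constant_prevalence_flagged(self):
        profiles = [self._prof(f"og{i}", 0.1 * (i + 1), 0.5) for i in range(5)]
        assert not comparative.threshold_prevalence_correlation(profiles).ok

    def test_never_ogs_excluded_and_min_count(self):
        profiles = [self._prof("a", None, 0.5), self._prof("b", 1.0, 0.5),
                    self._prof("c", 1.5, 0.9)]
        res = comparative.threshold_prevalence_correlation(profiles)
        assert not res.ok and res.n == 2

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(9)
        profiles = [
            self._prof(f"og{i}", float(rng.choice([0.5, 1.0, 1.5, 2.0])),
                       float(rng.integers(1, 10)) / 10)
            for i in range(50)
        ]
        res = comparative.threshold_prevalence_correlation(profiles)
        x = stats.rankdata([p.min_g for p in profiles])
        y = stats.rankdata([p.modern_prevalence for p in profiles])
        expected = np.corrcoef(x, y)[0, 1]
        assert res.rho == pytest.approx(expected, abs=1e-12)


class TestOverlapBreakdown:
    def test_fully_ancestral(self):
        out = comparative.overlap_breakdown({"a", "b", "c"}, {"sp": {"a"}}, {"a", "b"})
        assert out.counts == (2, 0, 0)

    def test_fully_novel(self):
        out = comparative.overlap_breakdown({"a"}, {"sp": {"b"}}, {"x", "y"})
        assert out.counts == (0, 0, 2)

    def test_partition_conservation(self):
        rng = np.random.default_rng(3)
        universe = [f"og{i}" for i in range(100)]
        lbca = set(rng.choice(universe, 30, replace=False))
        modern = {f"sp{k}": set(rng.choice(universe, 40, replace=False)) for k in range(5)}
        external = set(rng.choice(universe, 50, replace=False))
        out = comparative.overlap_breakdown(lbca, modern, external)
        assert sum(out.counts) == len(external)
        assert not (out.in_lbca & out.in_modern_only)
        assert not (out.in_lbca & out.in_none) and not (out.in_modern_only & out.in_none)


class TestModuleParsing:
    def test_two_single_ko_steps(self):
        md = comparative.parse_module("K00001 K00002")
        assert len(md.steps) == 2
        assert md.kos() == {"K00001", "K00002"}

    def test_grouped_or_then_step(self):
        md = comparative.parse_module("(K00001,K00002) K00003")
        ev = comparative.evaluate_module(md, {"K00002", "K00003"})
        assert ev.step_active == [True, True] and ev.completeness == 1.0

    def test_and_with_optional_component(self):
        md = comparative.parse_module("K00001+K00002-K00003")
        assert len(md.steps) == 1
        # truth table over all 8 subsets: K00003 must never matter
        for bits in itertools.product([0, 1], repeat=3):
            present = {k for k, b in zip(["K00001", "K00002", "K00003"], bits) if b}
            ev = comparative.evaluate_module(md, present)
            assert ev.any_active == (("K00001" in present) and ("K00002" in present))

    def test_and_unsatisfied(self):
        md = comparative.parse_module("K00001+K00002")
        assert not comparative.evaluate_module(md, {"K00001"}).any_active

    def test_unbalanced_paren_position(self):
        with pytest.raises(comparative.ModuleParseError):
            comparative.parse_module("(K00001,K00002 K00003")

    def test_bad_token_rejected(self):
        with pytest.raises(comparative.ModuleParseError):
            comparative.parse_module("K1 K00002")

    def test_round_trip_equivalence(self):
        raw = "((K00001,K00002)+K00003) K00004-K00005"
        md = comparative.parse_module(raw)
        md2 = comparative.parse_module(md.render())
        kos = sorted(md.kos())
        for bits in itertools.product([0, 1], repeat=len(kos)):
            present = {k for k, b in zip(kos, bits) if b}
            assert (
                comparative.evaluate_module(md, present).step_active
                == comparative.evaluate_module(md2, present).step_active
            )

    def _random_definition(self, rng):
        kos = [f"K{rng.integers(0, 99999):05d}" for _ in range(rng.integers(4, 8))]
        kos = list(dict.fromkeys(kos))

        def expr(depth, pool):
            if depth == 0 or len(pool) == 1 or rng.random() < 0.4:
                return pool[int(rng.integers(len(pool)))]
            cut = int(rng.integers(1, len(pool)))
            left, right = expr(depth - 1, pool[:cut]), expr(depth - 1, pool[cut:])
            op = rng.choice([",", "+"])
            text = f"{left}{op}{right}"
            return f"({text})" if rng.random() < 0.5 else text

        steps = []
        chunks = np.array_split(np.array(kos, dtype=object), rng.integers(1, 4))
        for chunk in chunks:
            if len(chunk):
                steps.append(expr(2, list(chunk)))
        return " ".join(steps)

    def _truth_table_oracle(self, text, present):
        """Independent evaluator: substitute booleans and eval with Python."""
        import re

        def step_eval(step):
            expr = re.sub(r"K\d{5}", lambda m: str(m.group() in present), step)
            expr = re.sub(r"-(True|False|\([^()]*\))", "", expr)  # optional parts
            while "-" in expr:
                expr = re.sub(r"-(True|False|\([^()]*\))", "", expr)
            expr = expr.replace(",", " or ").replace("+", " and ")
            return bool(eval(expr))

        # split top-level steps on spaces outside parentheses
        steps, depth, cur = [], 0, ""
        for ch in text:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            if ch == " " and depth == 0:
                if cur:
                    steps.append(cur)
                cur = ""
            else:
                cur += ch
        if cur:
            steps.append(cur)
        return [step_eval(s) for s in steps]

    def test_random_definitions_match_truth_table_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            text = self._random_definition(rng)
            md = comparative.parse_module(text)
            kos = sorted(md.kos())
            subsets = list(itertools.product([0, 1], repeat=len(kos)))
            if len(subsets) > 128:
                subsets = [subsets[i] for i in rng.choice(len(subsets), 128, replace=False)]
            for bits in subsets:
                present = {k for k, b in zip(kos, bits) if b}
                got = comparative.evaluate_module(md, present).step_active
                want = self._truth_table_oracle(text, present)
                assert got == want, f"{text} with {sorted(present)}"

    def test_evaluation_monotone_in_ko_set(self):
        rng = np.random.default_rng(43)
        for _ in range(15):
            text = self._random_definition(rng)
            md = comparative.parse_module(text)
            kos = sorted(md.kos())
            present = {k for k in kos if rng.random() < 0.5}
            base = comparative.evaluate_module(md, present)
            for extra in set(kos) - present:
                grown = comparative.evaluate_module(md, present | {extra})
                for before, after in zip(base.step_active, grown.step_active):
                    assert after or not before


class TestMapOgToKo:
    def test_modal_ko(self):
        df = pd.DataFrame(
            {"sequence": ["s1", "s2", "s3"], "og": ["OG1"] * 3,
             "ko": ["K00001", "K00001", "K00002"]})
        assert comparative.map_og_to_ko(df) == {"OG1": "K00001"}

    def test_singleton(self):
        df = pd.DataFrame({"sequence": ["s1"], "og": ["OG1"], "ko": ["K00009"]})
        assert comparative.map_og_to_ko(df) == {"OG1": "K00009"}

    def test_tie_breaks_lexicographic(self):
        df = pd.DataFrame(
            {"sequence": ["s1", "s2"], "og": ["OG1", "OG1"], "ko": ["K00002", "K00001"]})
        assert comparative.map_og_to_ko(df) == {"OG1": "K00001"}
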