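import numpy as np
import pandas as pd
import pytest

from helpers import exact_binom_tail, exact_fisher_greater
from immunoreo.pairs import StablePairSet
from immunoreo.signatures import (
    BinomialTestConfig,
    SignatureSet,
    binomial_population_p,
    build_signatures,
    call_updegs,
    rankcomp_updeg,
)


def make_background(pairs, n=20, threshold=0.99):
    return StablePairSet(pairs={p: 1.0 for p in pairs}, threshold=threshold, reference_n=n)


class TestBinomialPopulationP:
    def test_zero_successes_gives_one(self):
        for n in (1, 5, 50):
            assert binomial_population_p(0, n) == 1.0

    def test_all_samples_up_at_even_odds(self):
        assert binomial_population_p(10, 10) == pytest.approx(0.5**10, rel=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 7, 20, 35])
    def test_matches_exact_summation(self, n):
        for k in range(n + 1):
            expected = float(exact_binom_tail(k, n))
            assert binomial_population_p(k, n) == pytest.approx(expected, rel=1e-12)

    def test_nondefault_p0(self):
        cfg = BinomialTestConfig(P0=0.3)
        from fractions import Fraction
        expected = float(exact_binom_tail(4, 6, Fraction(3, 10)))
        assert binomial_population_p(4, 6, cfg) == pytest.approx(expected, rel=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        values = [binomial_population_p(k, 30) for k in range(31)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            binomial_population_p(5, 4)
        with pytest.raises(ValueError):
            binomial_population_p(0, 0)
        with pytest.raises(ValueError):
            BinomialTestConfig(P0=0.0)


class TestRankCompUpdeg:
    def test_sample_matching_background_is_null(self):
        # G up against 5 partners, down against 5 in the background; the
        # sample reproduces the reference ordering exactly.
        ups = [f"L{i}" for i in range(5)]
        downs = [f"H{i}" for i in range(5)]
        bg = make_background([("G", l) for l in ups] + [(h, "G") for h in downs])
        expr = {"G": 10.0}
        expr.update({l: 1.0 for l in ups})
        expr.update({h: 100.0 for h in downs})
        sample = pd.Series(expr, name="s")
        calls = rankcomp_updeg(sample, ["G"], bg)
        assert not calls.loc["G", "up"]
        assert calls.loc["G", "adjusted_p"] > 0.3

    def test_pvalue_matches_exact_enumeration(self):
        # background: 2 pairs with G above, 38 below; the sample reverses
        # most of them (30 above, 10 below)
        ups = [f"L{i}" for i in range(2)]
        downs = [f"H{i}" for i in range(38)]
        bg = make_background([("G", l) for l in ups] + [(h, "G") for h in downs])
        expr = {"G": 50.0}
        expr.update({l: 1.0 for l in ups})          # G above: stays above
        for i, h in enumerate(downs):
            expr[h] = 1.0 if i < 28 else 100.0       # 28 reversals
        sample = pd.Series(expr, name="s")
        calls = rankcomp_updeg(sample, ["G"], bg)
        expected = float(exact_fisher_greater(30, 10, 2, 38))
        assert calls.loc["G", "adjusted_p"] == pytest.approx(expected, rel=1e-10)
        assert calls.loc["G", "up"]

    def test_all_tied_partners_are_zero_evidence(self):
        bg = make_background([("G", "L1"), ("H1", "G")])
        sample = pd.Series({"G": 5.0, "L1": 5.0, "H1": 5.0}, name="s")
        calls = rankcomp_updeg(sample, ["G"], bg)
        assert not calls.loc["G", "up"]

    def test_candidate_without_background_pairs(self, caplog):
        bg = make_background([("A", "B")])
        sample = pd.Series({"A": 1.0, "B": 2.0, "X": 3.0}, name="s")
        calls = rankcomp_updeg(sample, ["X"], bg)
        assert calls.loc["X", "adjusted_p"] == 1.0
        assert not calls.loc["X", "up"]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(12)]
        ref = pd.DataFrame(rng.uniform(1, 100, (12, 10)), index=genes)
        from immunoreo.pairs import find_stable_pairs
        bg = find_stable_pairs(ref, genes, threshold=0.8)
        sample = pd.Series(rng.uniform(1, 100, 12), index=genes, name="s")
        base = rankcomp_updeg(sample, genes[:4], bg)
        warped = np.log(sample * 3.7 + 1)
        again = rankcomp_updeg(warped, genes[:4], bg)
        pd.testing.assert_frame_equal(base, again)

    def test_one_round_is_the_default(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(15)]
        ref = pd.DataFrame(rng.uniform(1, 100, (15, 12)), index=genes)
        from immunoreo.pairs import find_stable_pairs
        bg = find_stable_pairs(ref, genes, threshold=0.75)
        cohort = pd.DataFrame(rng.uniform(1, 100, (15, 5)), index=genes)
        default_flags, default_p = call_updegs(cohort, genes[:8], bg)
        one_flags, one_p = call_updegs(cohort, genes[:8], bg, max_rounds=1)
        pd.testing.assert_frame_equal(default_flags, one_flags)
        pd.testing.assert_frame_equal(default_p, one_p)

    def test_iterative_refinement_reaches_a_fixed_point(self):
        # with iteration, partners already called up are excluded from the
        # null background; verify the returned flags are self-consistent
        # by recomputing one sample's counts under that exclusion
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(20)]
        ref = pd.DataFrame(rng.uniform(1, 100, (20, 15)), index=genes)
        from immunoreo.pairs import find_stable_pairs
        from immunoreo._stats import bh_adjust, fisher_greater_p
        bg = find_stable_pairs(ref, genes, threshold=0.7)
        sample = pd.Series(rng.uniform(1, 100, 20), index=genes, name="q")
        cands = genes[:10]
        flags, _ = call_updegs(sample.to_frame(), cands, bg, max_rounds=10)
        up = set(flags.index[flags.iloc[:, 0]])
        ps = []
        fracs = []
        for g in cands:
            n_gt = n_lt = c_gt = c_lt = 0
            for (x, y) in bg.pairs:
                other = y if x == g else x if y == g else None
                if other is None or other in up:
                    continue
                if x == g:
                    n_gt += 1
                else:
                    n_lt += 1
                c_gt += sample[g] > sample[other]
                c_lt += sample[g] < sample[other]
            if n_gt + n_lt == 0:
                ps.append(1.0); fracs.append((0.0, 1.0))
                continue
            ps.append(float(fisher_greater_p(c_gt, c_lt, n_gt, n_lt)))
            fracs.append((
                c_gt / (c_gt + c_lt) if c_gt + c_lt else 0.0,
                n_gt / (n_gt + n_lt),
            ))
        adj = bh_adjust(ps)
        for g, ap, (sf, bf) in zip(cands, adj, fracs):
            assert (g in up) == (ap < 0.05 and sf > bf), g

    def test_raising_fdr_never_removes_up_flags(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(15)]
        ref = pd.DataFrame(rng.uniform(1, 100, (15, 12)), index=genes)
        from immunoreo.pairs import find_stable_pairs
        bg = find_stable_pairs(ref, genes, threshold=0.75)
        cohort = pd.DataFrame(rng.uniform(1, 100, (15, 6)), index=genes)
        strict, _ = call_updegs(cohort, genes[:6], bg, individual_fdr=0.05)
        loose, _ = call_updegs(cohort, genes[:6], bg, individual_fdr=0.25)
        assert (loose | ~strict).all().all()  # strict up implies loose up


class TestBuildSignatures:
    def _flags(self, genes, samples, up_matrix):
        return pd.DataFrame(
            np.asarray(up_matrix, dtype=bool),
            index=pd.Index(genes, name="gene_id"),
            columns=[f"s{j}" for j in range(samples)],
        )

    def test_gene_up_in_all_samples_is_retained(self):
        flags = {"B": self._flags(["G1"], 10, [[True] * 10])}
        sig = build_signatures({"B": ["G1"]}, flags)
        assert sig.entries["B"] == ["G1"]
        assert sig.provenance["B"]["G1"] == pytest.approx(0.5**10, rel=1e-9)

    def test_gene_up_in_half_the_samples_is_dropped(self):
        flags = {"B": self._flags(["G1"], 10, [[True] * 5 + [False] * 5])}
        sig = build_signatures({"B": ["G1"]}, flags)
        assert sig.entries["B"] == []
        # population p for k=5, n=10 is ~0.623
        assert float(exact_binom_tail(5, 10)) == pytest.approx(0.623, abs=0.001)

    def test_gene_shared_by_two_cell_types_removed_from_both(self):
        flags = {
            "B": self._flags(["G1", "G2"], 10, [[True] * 10, [True] * 10]),
            "T": self._flags(["G1", "G3"], 10, [[True] * 10, [True] * 10]),
        }
        sig = build_signatures({"B": ["G1", "G2"], "T": ["G1", "G3"]}, flags)
        assert sig.entries == {"B": ["G2"], "T": ["G3"]}

    def test_signatures_disjoint_and_subset_of_candidates(self, small_pipeline):
        _, signatures, _, (_, _, _, markers) = small_pipeline
        seen = set()
        for ct, genes in signatures.entries.items():
            assert set(genes) <= set(markers[ct])
            assert not (set(genes) & seen)
            seen |= set(genes)

    def test_raising_population_fdr_only_adds_genes(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(8)]
        flags = {"B": self._flags(genes, 12, rng.random((8, 12)) < 0.7)}
        strict = build_signatures({"B": genes}, flags, BinomialTestConfig(population_fdr=0.01))
        loose = build_signatures({"B": genes}, flags, BinomialTestConfig(population_fdr=0.20))
        assert set(strict.entries["B"]) <= set(loose.entries["B"])

    def test_missing_cohort_rejected(self):
        with pytest.raises(ValueError, match="no profiled samples"):
            build_signatures({"B": ["G1"]}, {})

    def test_signature_set_rejects_overlap(self):
        with pytest.raises(ValueError, match="assigned to both"):
            SignatureSet(entries={"B": ["G1"], "T": ["G1"]})

    def test_json_round_trip(self, tmp_path, small_pipeline):
        _, signatures, _, _ = small_pipeline
        path = tmp_path / "sig.json"
        signatures.to_json(path)
        back = SignatureSet.from_json(path)
        assert back.entries == signatures.entries
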