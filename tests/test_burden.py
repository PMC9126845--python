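"""Mutability model, binomial burden test, Q-Q points, over-representation."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import hypergeom

from hdlburden import (
    GeneMutability,
    GeneSet,
    MutationRateTable,
    binomial_burden,
    coverage_adjust,
    expected_counts,
    gene_mutability_from_cds,
    overrepresentation,
    qq_points,
    run_burden,
    snv_mutability_classes,
    snv_mutability_from_cds,
)
from hdlburden.burden import BASES

from test_filtering import make_variant


def uniform_rate_table(rate=1e-8):
    return MutationRateTable(
        {
            (f, r, t, a): rate
            for f in BASES
            for r in BASES
            for t in BASES
            for a in BASES
            if a != r
        }
    )


def enumerate_classes_oracle(cds_with_flanks, rates):
    """Brute-force oracle: mutate the full CDS base by base, translate the
    whole protein with Biopython, and classify by comparing proteins."""
    seq = cds_with_flanks.upper()
    cds = seq[1:-1]
    old_prot = str(Seq(cds).translate())
    out = {"LoF": 0.0, "missense": 0.0, "synonymous": 0.0, "total": 0.0}
    for i, ref in enumerate(cds):
        for alt in BASES:
            if alt == ref:
                continue
            rate = rates[(seq[i], ref, seq[i + 2], alt)]
            out["total"] += rate
            new_cds = cds[:i] + alt + cds[i + 1 :]
            new_prot = str(Seq(new_cds).translate())
            j = i // 3
            if j == 0 and cds[:3] == "ATG" and new_cds[:3] != "ATG":
                out["LoF"] += rate
            elif old_prot[j] == "*" and new_prot[j] != "*":
                out["LoF"] += rate
            elif new_prot[j] == "*" and old_prot[j] != "*":
                out["LoF"] += rate
            elif old_prot[j] == new_prot[j]:
                out["synonymous"] += rate
            else:
                out["missense"] += rate
    return out


class TestSnvMutability:
    def test_class_partition_conserves_total(self, rate_table, rng):
        codons = [a + b + c for a in BASES for b in BASES for c in BASES]
        for _ in range(5):
            body = "".join(rng.choice(codons) for _ in range(rng.integers(5, 20)))
            cds = "A" + "ATG" + body + "C"
            if (len(cds) - 2) % 3:
                continue
            classes = snv_mutability_classes(cds, rate_table)
            parts = classes["LoF"] + classes["missense"] + classes["synonymous"]
            assert parts == pytest.approx(classes["total"], rel=1e-12)

    def test_matches_brute_force_enumeration(self, rate_table, rng):
        codons = [a + b + c for a in BASES for b in BASES for c in BASES]
        for _ in range(3):
            body = "".join(rng.choice(codons) for _ in range(12))
            cds = "G" + "ATG" + body + "TAA" + "T"
            got = snv_mutability_classes(cds, rate_table)
            want = enumerate_classes_oracle(cds, rate_table)
            for k in ("LoF", "missense", "synonymous", "total"):
                assert got[k] == pytest.approx(want[k], rel=1e-12)

    def test_single_trp_codon_stop_gain_is_two_r(self):
        # CCC codons are 2+ substitutions from any stop; TGG -> TAG / TGA
        # are the only stop-gains, so LoF mutability is exactly 2r.
        rates = uniform_rate_table(rate=3e-9)
        cds = "A" + "CCC" + "TGG" + "CCC" + "A"
        assert snv_mutability_from_cds(cds, rates, "LoF") == pytest.approx(
            2 * 3e-9, rel=1e-12
        )

    def test_ggg_missense_equals_enumerated_sum(self, rate_table):
        cds = "A" + "CCC" + "GGG" + "CCC" + "A"
        want = enumerate_classes_oracle(cds, rate_table)
        got = snv_mutability_from_cds(cds, rate_table, "missense")
        assert got == pytest.approx(want["missense"], rel=1e-12)

    def test_bad_length_rejected(self, rate_table):
        with pytest.raises(ValueError, match="divisible"):
            snv_mutability_classes("AATGCA", rate_table)  # CDS length 4

    def test_ambiguity_code_rejected(self, rate_table):
        with pytest.raises(ValueError, match="ambiguity"):
            snv_mutability_classes("AATGNNNTAAC", rate_table)


class TestGeneMutability:
    def test_coverage_one_unchanged(self):
        m = GeneMutability(gene="G", lof=1e-6, dmis=2e-6)
        assert coverage_adjust(m, 1.0).adjusted_damaging == m.adjusted_damaging

    def test_coverage_half_halves(self):
        m = GeneMutability(gene="G", lof=1e-6, dmis=2e-6)
        adj = coverage_adjust(m, 0.5)
        assert adj.adjusted_damaging == pytest.approx(0.5 * m.damaging)

    def test_zero_coverage_excluded_with_warning(self, caplog):
        m = GeneMutability(gene="G", lof=1e-6, dmis=2e-6)
        with caplog.at_level("WARNING"):
            z = coverage_adjust(m, 0.0)
        assert z.adjusted_damaging == 0.0
        with pytest.raises(ValueError, match="zero"):
            expected_counts(10, [z])

    def test_indel_splice_term_additive(self, rate_table):
        cds = "G" + "ATG" + "CCCTGGAAA" * 4 + "TAA" + "T"
        plain = gene_mutability_from_cds("G", cds, rate_table, indel_splice_factor=0.0)
        boosted = gene_mutability_from_cds("G", cds, rate_table, indel_splice_factor=1.25)
        assert boosted.lof == pytest.approx(2.25 * plain.lof)
        assert boosted.dmis == plain.dmis


class TestExpectedCounts:
    def test_worked_example(self):
        genes = [
            GeneMutability(gene=g, lof=m, dmis=0.0)
            for g, m in (("a", 0.2), ("b", 0.3), ("c", 0.5))
        ]
        out = expected_counts(10, genes)
        assert out["a"][1] == pytest.approx(2.0)
        assert out["b"][1] == pytest.approx(3.0)
        assert out["c"][1] == pytest.approx(5.0)

    def test_single_gene_gets_all(self):
        (g,) = [GeneMutability(gene="only", lof=1e-6, dmis=0.0)]
        assert expected_counts(7, [g])["only"] == (1.0, 7.0)

    def test_normalization_identity(self, rng):
        genes = [
            GeneMutability(gene=f"g{i}", lof=float(rng.uniform(1e-7, 1e-5)), dmis=0.0)
            for i in range(137)
        ]
        out = expected_counts(333, genes)
        assert sum(e for _, e in out.values()) == pytest.approx(333, abs=1e-12)


def binomial_tail_oracle(observed, N, p):
    """Exhaustive term-by-term summation of the upper binomial tail."""
    return sum(math.comb(N, k) * p**k * (1 - p) ** (N - k) for k in range(observed, N + 1))


class TestBinomialBurden:
    def test_observed_zero_is_one(self):
        assert binomial_burden(0, 10, 0.1) == 1.0

    def test_worked_example(self):
        assert round(binomial_burden(3, 10, 0.1), 4) == 0.0702
        assert binomial_burden(3, 10, 0.1) == pytest.approx(
            binomial_tail_oracle(3, 10, 0.1), rel=1e-12
        )

    def test_degenerate_p_one(self):
        assert binomial_burden(10, 10, 1.0) == 1.0

    def test_observed_above_n_rejected(self):
        with pytest.raises(ValueError):
            binomial_burden(11, 10, 0.1)

    def test_oracle_equivalence_randomized_grid(self, rng):
        """Survival-function path matches exhaustive summation to 1e-10
        relative error for N <= 1000."""
        for _ in range(60):
            N = int(rng.integers(1, 1001))
            p = float(10 ** rng.uniform(-6, -0.05))
            observed = int(rng.integers(0, min(N, 40) + 1))
            got = binomial_burden(observed, N, p)
            want = binomial_tail_oracle(observed, N, p)
            if want > 0:
                assert got == pytest.approx(want, rel=1e-10)

    def test_monotone_in_observed_and_p(self):
        ps = [binomial_burden(k, 50, 0.05) for k in range(1, 10)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        qs = [binomial_burden(5, 50, p) for p in (0.01, 0.05, 0.2, 0.5)]
        assert all(a < b for a, b in zip(qs, qs[1:]))


class TestRunBurden:
    def test_single_gene_p_one(self):
        gene = GeneMutability(gene="GENEA", lof=1e-6, dmis=1e-6)
        vs = [make_variant(pos=i, gene="GENEA") for i in range(1, 6)]
        (result,) = run_burden(vs, [gene])
        assert result.p_i == 1.0
        assert result.p_value == 1.0

    def test_null_calibration_and_conservation(self, null_burden_run):
        cohort, kept, tally, results = null_burden_run
        N = sum(r.observed for r in results)
        assert abs(sum(r.expected for r in results) - N) <= 1e-12 * max(N, 1)
        frac = np.mean([r.p_value < 0.05 for r in results])
        band = 3 * np.sqrt(0.05 * 0.95 / len(results))
        assert abs(frac - 0.05) <= band

    def test_results_sorted_by_p(self, null_burden_run):
        *_, results = null_burden_run
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)


class TestQQ:
    def test_single_median_p(self):
        pts = qq_points([0.5])
        assert pts[0] == pytest.approx([math.log10(2), math.log10(2)])

    def test_uniform_grid_on_diagonal(self):
        n = 9
        grid = [(i + 1) / (n + 1) for i in range(n)]
        pts = qq_points(grid)
        assert np.allclose(pts[:, 0], pts[:, 1])

    def test_uniform_simulation_close_to_diagonal(self, rng):
        p = rng.uniform(size=1000)
        pts = qq_points(p)
        assert np.median(np.abs(pts[:, 1] - pts[:, 0])) < 0.1

    def test_zero_p_clamped(self, caplog):
        with caplog.at_level("WARNING"):
            pts = qq_points([0.0, 0.5])
        assert np.isfinite(pts).all()


class TestOverrepresentation:
    def _sets(self, members_by_name):
        return [
            GeneSet(name=n, description="d", members=frozenset(m))
            for n, m in members_by_name.items()
        ]

    def test_at_expectation_not_enriched(self):
        hit = [f"h{i}" for i in range(10)]
        members = hit[:2] + [f"m{i}" for i in range(18)]
        (res,) = overrepresentation(hit, self._sets({"S": members}), universe=100)
        assert res.expected == pytest.approx(2.0)
        assert res.fold == pytest.approx(1.0)
        assert res.p_value > 0.5

    def test_enriched_matches_hypergeometric_tail(self):
        hit = [f"h{i}" for i in range(10)]
        members = hit[:8] + [f"m{i}" for i in range(12)]
        (res,) = overrepresentation(hit, self._sets({"S": members}), universe=100)
        assert res.hits == 8
        assert res.fold == pytest.approx(4.0)
        oracle = sum(hypergeom.pmf(k, 100, 20, 10) for k in range(8, 11))
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_single_set_q_equals_p(self):
        hit = ["a", "b"]
        (res,) = overrepresentation(hit, self._sets({"S": ["a", "x", "y"]}), universe=50)
        assert res.q_value == pytest.approx(res.p_value)

    def test_bh_step_up_monotone(self, rng):
        universe = [f"g{i}" for i in range(200)]
        hit = list(rng.choice(universe, size=20, replace=False))
        sets = self._sets(
            {
                f"S{j}": rng.choice(universe, size=int(rng.integers(5, 40)), replace=False)
                for j in range(12)
            }
        )
        results = overrepresentation(hit, sets, universe=200)
        by_p = sorted(results, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in results)

    def test_set_larger_than_universe_rejected(self):
        sets = self._sets({"S": [f"m{i}" for i in range(30)]})
        with pytest.raises(ValueError, match="universe"):
            overrepresentation(["a"], sets, universe=20)
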