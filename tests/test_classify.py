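"""Consensus damage classification: votes, percentiles, classes, tallies."""

import numpy as np
import pytest

from hdlburden import (
    DamageAssessment,
    Participant,
    assess_variants,
    carrier_association,
    damage_vote_count,
    damaging_carrier_ids,
    group_carrier_percentages,
    per_gene_damaging_counts,
    per_person_damaging_histogram,
    percentile_classify,
)
from hdlburden.classify import DAMAGING_CLASSES, is_unequivocal_pathogenic
from hdlburden.records import PREDICTION_TOOLS

from test_filtering import make_variant


def votes(n_damaging=0, n_equivocal=0, n_missing=0):
    calls = (
        ["damaging"] * n_damaging
        + ["equivocal"] * n_equivocal
        + ["missing"] * n_missing
    )
    calls += ["tolerated"] * (10 - len(calls))
    return dict(zip(PREDICTION_TOOLS, calls))


class TestVoteCount:
    def test_all_damaging_is_ten(self):
        assert damage_vote_count(votes(n_damaging=10)) == 10.0

    def test_equivocal_half_point(self):
        assert damage_vote_count(votes(n_damaging=9, n_equivocal=1)) == 9.5

    def test_all_missing_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert damage_vote_count(votes(n_missing=10)) == 0.0
        assert "missing" in caplog.text

    def test_unconfigured_tool_rejected(self):
        bad = votes(n_damaging=10)
        bad["CADD"] = bad.pop(PREDICTION_TOOLS[0])
        with pytest.raises(ValueError, match="CADD"):
            damage_vote_count(bad)

    def test_missing_tool_rejected(self):
        partial = votes(n_damaging=10)
        del partial[PREDICTION_TOOLS[0]]
        with pytest.raises(ValueError, match="absent"):
            damage_vote_count(partial)


def ladder(n=20):
    """Assessments with distinct counts 0, 0.5, ..., 9.5: mid-rank percentile
    of the k-th is (k + 0.5) / n."""
    return [DamageAssessment(key=f"v{k}", vote_count=0.5 * k) for k in range(n)]


class TestPercentileClassify:
    def test_high_percentile_probably_damaging(self):
        a = percentile_classify(ladder(), clinvar={})
        # counts 16..19 have percentiles 0.825..0.975
        top = [x for x in a if x.vote_count >= 8.0]
        assert all(x.klass == "probably_damaging" for x in top)

    def test_midband_with_pathogenic_entry_promoted(self):
        a = percentile_classify(ladder(), clinvar={"v12": "Pathogenic"})
        v12 = next(x for x in a if x.key == "v12")
        assert 0.5 < v12.percentile < 0.8
        assert v12.klass == "pathogenic"

    def test_low_percentile_stays_benign_despite_clinvar(self):
        a = percentile_classify(ladder(), clinvar={"v8": "Pathogenic"})
        v8 = next(x for x in a if x.key == "v8")
        assert v8.percentile < 0.5
        assert v8.klass == "likely_benign"

    def test_midband_without_clinvar_undetermined(self):
        a = percentile_classify(ladder(), clinvar={})
        v12 = next(x for x in a if x.key == "v12")
        assert v12.klass == "undetermined"

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            percentile_classify([], clinvar={})

    def test_duplication_invariance(self):
        single = percentile_classify(ladder(), clinvar={})
        doubled = [
            DamageAssessment(key=f"{a.key}-{rep}", vote_count=a.vote_count)
            for rep in (1, 2)
            for a in ladder()
        ]
        percentile_classify(doubled, clinvar={})
        pct_single = {a.vote_count: a.percentile for a in single}
        for a in doubled:
            assert a.percentile == pytest.approx(pct_single[a.vote_count])

    def test_monotone_in_single_vote(self, rng):
        """Raising one tool's vote never lowers the classification."""
        order = {"likely_benign": 0, "undetermined": 1, "probably_damaging": 2, "pathogenic": 3}
        ups = {"tolerated": "equivocal", "missing": "equivocal", "equivocal": "damaging"}
        for _ in range(20):
            vs = [
                make_variant(pos=100 + i, votes=dict(zip(
                    PREDICTION_TOOLS,
                    rng.choice(["damaging", "tolerated", "equivocal", "missing"], size=10),
                )))
                for i in range(25)
            ]
            before = assess_variants(vs)
            target = vs[int(rng.integers(len(vs)))]
            tool = PREDICTION_TOOLS[int(rng.integers(10))]
            if target.votes[tool] == "damaging":
                continue
            target.votes[tool] = ups[target.votes[tool]]
            after = assess_variants(vs)
            assert order[after[target.key].klass] >= order[before[target.key].klass]

    def test_unequivocal_label_semantics(self):
        assert is_unequivocal_pathogenic("Pathogenic")
        assert is_unequivocal_pathogenic("Likely pathogenic")
        assert not is_unequivocal_pathogenic("Likely benign")
        assert not is_unequivocal_pathogenic("Conflicting interpretations of pathogenicity")
        assert not is_unequivocal_pathogenic("Uncertain significance")
        assert not is_unequivocal_pathogenic(None)


def _classified_fixture():
    """Three genes; vA damaging with 3 carriers, vB damaging 1 carrier,
    vC undetermined, vD benign."""
    vA = make_variant(pos=1, gene="GA", votes=votes(n_damaging=10),
                      genotypes={"S1": "het", "S2": "het", "S3": "hom"})
    vB = make_variant(pos=2, gene="GB", votes=votes(n_damaging=9),
                      genotypes={"S1": "het"})
    vC = make_variant(pos=3, gene="GA", votes=votes(n_damaging=5),
                      genotypes={"S2": "het"})
    vD = make_variant(pos=4, gene="GC", votes=votes(), genotypes={"S4": "het"})
    filler = [make_variant(pos=10 + i, gene="GZ", votes=votes(), genotypes={})
              for i in range(10)]
    filler += [make_variant(pos=30 + i, gene="GZ", votes=votes(n_damaging=6),
                            genotypes={}) for i in range(6)]
    variants = [vA, vB, vC, vD] + filler
    assessments = assess_variants(variants)
    assert assessments[vA.key].klass in DAMAGING_CLASSES
    assert assessments[vB.key].klass in DAMAGING_CLASSES
    assert assessments[vC.key].klass == "undetermined"
    return variants, assessments


class TestTallies:
    def test_occurrences_counted_per_carrier(self):
        variants, assessments = _classified_fixture()
        counts = per_gene_damaging_counts(variants, assessments, ["GA", "GB", "GC"])
        # vA has 3 carriers (hom counts once); vC is undetermined -> 0 for it
        assert counts == {"GA": 3, "GB": 1}

    def test_empty_gene_list_empty_counts(self):
        variants, assessments = _classified_fixture()
        assert per_gene_damaging_counts(variants, assessments, []) == {}

    def test_histogram_counts_variants_not_genes(self):
        variants, assessments = _classified_fixture()
        hist = per_person_damaging_histogram(
            variants, assessments, ["GA", "GB"], ["S1", "S2", "S3", "S4"]
        )
        # S1 carries vA+vB (2), S2 and S3 carry vA (1 each), S4 none
        assert hist == {2: 1, 1: 2, 0: 1}
        assert sum(hist.values()) == 4

    def test_histogram_no_damaging_all_zero(self):
        v = make_variant(votes=votes())
        filler = [make_variant(pos=10 + i, votes=votes(n_damaging=10)) for i in range(4)]
        assessments = assess_variants([v] + filler)
        hist = per_person_damaging_histogram([v], assessments, ["GENEA"], ["S1", "S2"])
        assert hist == {0: 2}

    def test_group_carrier_percentages(self):
        ps = []
        for g, (n, n_car) in {1: (80, 46), 2: (23, 8), 3: (77, 45), 4: (24, 11)}.items():
            for i in range(n):
                p = Participant(pid=f"g{g}i{i}", sex="M", age=50)
                p.group = g
                ps.append(p)
        carriers = {f"g{g}i{i}" for g, (n, n_car) in
                    {1: (80, 46), 2: (23, 8), 3: (77, 45), 4: (24, 11)}.items()
                    for i in range(n_car)}
        pct = group_carrier_percentages(ps, carriers)
        assert pct == {1: 57.5, 2: 34.8, 3: 58.4, 4: 45.8}


class TestCarrierAssociation:
    def _participants(self, carrier_values, noncarrier_values):
        ps = []
        for i, v in enumerate(carrier_values):
            ps.append(Participant(pid=f"C{i}", sex="M", age=50, ldl=float(v)))
        for i, v in enumerate(noncarrier_values):
            ps.append(Participant(pid=f"N{i}", sex="M", age=50, ldl=float(v)))
        return ps

    def _variants_for_carriers(self, n_carriers):
        damaging = make_variant(
            pos=1, gene="GA", votes=votes(n_damaging=10),
            genotypes={f"C{i}": "het" for i in range(n_carriers)},
        )
        filler = [make_variant(pos=10 + i, gene="GZ", votes=votes(), genotypes={})
                  for i in range(9)]
        vs = [damaging] + filler
        return vs, assess_variants(vs)

    def test_identical_values_p_one(self):
        ps = self._participants([100] * 5, [100] * 5)
        vs, a = self._variants_for_carriers(5)
        result = carrier_association(vs, a, ["GA"], ps, "ldl")
        assert result.p_value == 1.0
        assert result.n_carriers == 5 and result.n_noncarriers == 5

    def test_all_carriers_rejected(self):
        ps = self._participants([100] * 5, [])
        vs, a = self._variants_for_carriers(5)
        with pytest.raises(ValueError, match="noncarrier"):
            carrier_association(vs, a, ["GA"], ps, "ldl")

    def test_planted_shift_recovered_with_power(self, rng):
        """-30 mg/dl LDL shift in 38 of 204: detected in >= 80% of replicates."""
        hits = 0
        shifts = []
        n_rep = 100
        for _ in range(n_rep):
            carriers = np.maximum(rng.normal(101, 45, 38), 1.0)
            noncarriers = np.maximum(rng.normal(131, 45, 166), 1.0)
            ps = self._participants(carriers, noncarriers)
            vs, a = self._variants_for_carriers(38)
            res = carrier_association(vs, a, ["GA"], ps, "ldl", transform="sqrt")
            hits += res.p_value < 0.05
            shifts.append(res.carrier_mean - res.noncarrier_mean)
        assert hits >= 80
        se = np.std(shifts, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(shifts) - (-30.0)) < 2 * se + 1.0
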