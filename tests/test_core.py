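import numpy as np
import pytest

from imap import core
from imap.core import (
    ExpectedGenotypeField,
    InsufficientPairTrios,
    JointGenotypeTable,
    apply_correction_and_normalize,
    correction_factors,
    expected_field,
    imap_statistic,
    joint_table,
    mendelian_offspring_probs,
    normalized_expected_field,
    score_all_pairs,
    score_pair,
)
from imap.genotype_io import MISSING, extract_trios

import oracles
from conftest import random_trio_dataset


# the six distinct parental combinations and their offspring distributions
MENDEL_ROWS = [
    ((0, 0), (1.0, 0.0, 0.0)),
    ((0, 1), (0.5, 0.5, 0.0)),
    ((0, 2), (0.0, 1.0, 0.0)),
    ((1, 1), (0.25, 0.5, 0.25)),
    ((1, 2), (0.0, 0.5, 0.5)),
    ((2, 2), (0.0, 0.0, 1.0)),
]


class TestMendelianProbs:
    @pytest.mark.parametrize("parents,expected", MENDEL_ROWS)
    def test_matches_transmission_law_exactly(self, parents, expected):
        assert mendelian_offspring_probs(*parents).tolist() == list(expected)
        assert mendelian_offspring_probs(*parents[::-1]).tolist() == list(expected)

    def test_missing_parent_rejected(self):
        with pytest.raises(ValueError, match="mask missing"):
            mendelian_offspring_probs(MISSING, 1)


class TestExpectedField:
    def test_values_and_invalid_entries(self, rng):
        gm, ped = random_trio_dataset(rng, n_trios=6, n_markers=5, missing_rate=0.2)
        trios = extract_trios(gm, ped)
        field = expected_field(gm, trios)
        field.validate()
        g = gm.genotypes
        for t in range(trios.n_trios):
            for j in range(gm.n_markers):
                if trios.usable[t, j]:
                    want = mendelian_offspring_probs(
                        g[trios.father[t], j], g[trios.mother[t], j]
                    )
                    np.testing.assert_allclose(field.probs[t, j], want)
                else:
                    assert field.probs[t, j].tolist() == [0, 0, 0]

    def test_aa_by_aa_parents_give_certain_het(self, rng):
        gm, ped = random_trio_dataset(rng, n_trios=1, n_markers=1, missing_rate=0.0)
        i = gm.individual_index()
        gm.genotypes[i["f0"], 0] = 0
        gm.genotypes[i["m0"], 0] = 2
        gm.genotypes[i["c0"], 0] = 1
        trios = extract_trios(gm, ped)
        field = expected_field(gm, trios)
        assert field.probs[0, 0].tolist() == [0.0, 1.0, 0.0]


def _ten_het_trios(children):
    """10 trios, 1 marker, all parents Aa x Aa, children as given."""
    import pandas as pd
    from imap.genotype_io import GenotypeMatrix, PedigreeTable
    from conftest import make_markers

    n = len(children)
    geno = np.concatenate([children, [1] * n, [1] * n]).astype(np.int8).reshape(3 * n, 1)
    ids = [f"c{t}" for t in range(n)] + [f"f{t}" for t in range(n)] + [f"m{t}" for t in range(n)]
    gm = GenotypeMatrix(geno, ids, make_markers(1))
    rows = [{"individual_id": f"c{t}", "father_id": f"f{t}", "mother_id": f"m{t}"} for t in range(n)]
    rows += [
        {"individual_id": p, "father_id": None, "mother_id": None}
        for t in range(n) for p in (f"f{t}", f"m{t}")
    ]
    ped = PedigreeTable(pd.DataFrame(rows))
    return gm, extract_trios(gm, ped)


class TestCorrection:
    def test_factors_are_elementwise_observed_over_expected(self):
        # observed (5, 3, 2) vs Mendelian expectation (2.5, 5, 2.5) over 10 trios
        gm, trios = _ten_het_trios([0] * 5 + [1] * 3 + [2] * 2)
        field = expected_field(gm, trios)
        cf = correction_factors(gm, trios, field)
        np.testing.assert_allclose(cf.factors[0], [2.0, 0.6, 0.8])

    def test_no_distortion_gives_unit_factors(self):
        # an exactly Mendelian split (2, 4, 2) over 8 Aa x Aa trios
        gm, trios = _ten_het_trios([0, 0, 1, 1, 1, 1, 2, 2])
        field = expected_field(gm, trios)
        cf = correction_factors(gm, trios, field)
        np.testing.assert_allclose(cf.factors[0], [1.0, 1.0, 1.0])

    def test_never_expected_never_observed_factor_is_one(self, rng):
        gm, ped = random_trio_dataset(rng, n_trios=4, n_markers=1, missing_rate=0.0)
        i = gm.individual_index()
        for t in range(4):  # all AA x AA: only genotype 0 possible
            for who in ("c", "f", "m"):
                gm.genotypes[i[f"{who}{t}"], 0] = 0
        trios = extract_trios(gm, ped)
        cf = correction_factors(gm, trios, expected_field(gm, trios))
        assert cf.factors[0, 1] == 1.0 and cf.factors[0, 2] == 1.0

    def test_normalization_hand_example(self):
        probs = np.array([[[0.25, 0.5, 0.25]]])
        usable = np.array([[True]])
        field = ExpectedGenotypeField(probs, usable, "mendelian")
        cf = core.CorrectionFactors(np.array([[2.0, 0.6, 0.8]]))
        out = apply_correction_and_normalize(field, cf)
        np.testing.assert_allclose(out.probs[0, 0], [0.5, 0.3, 0.2])

    def test_unit_factors_are_identity(self, rng):
        gm, ped = random_trio_dataset(rng, n_trios=5, n_markers=3, missing_rate=0.1)
        trios = extract_trios(gm, ped)
        field = expected_field(gm, trios)
        out = apply_correction_and_normalize(field, core.CorrectionFactors(np.ones((3, 3))))
        np.testing.assert_allclose(out.probs, field.probs)

    def test_certain_genotype_preserved(self):
        field = ExpectedGenotypeField(np.array([[[1.0, 0, 0]]]), np.array([[True]]), "mendelian")
        out = apply_correction_and_normalize(field, core.CorrectionFactors(np.array([[3.7, 1, 1]])))
        np.testing.assert_allclose(out.probs[0, 0], [1, 0, 0])

    def test_correction_fixed_point_on_simulated_data(self, null_qc):
        """After correction, sample-wide expected genotype frequencies equal
        the observed ones at every marker (the point of the correction)."""
        gm, trios = null_qc
        field = normalized_expected_field(gm, trios)
        cg = gm.genotypes[trios.child]
        for g in range(3):
            obs = ((cg == g) & trios.usable).sum(axis=0)
            exp = field.probs[:, :, g].sum(axis=0)
            np.testing.assert_allclose(obs, exp, atol=1e-6)


class TestJointTableAndStatistic:
    def test_single_trio_hand_example(self):
        probs = np.zeros((1, 2, 3))
        probs[0, 0] = [1, 0, 0]
        probs[0, 1] = [0.5, 0.5, 0]
        field = ExpectedGenotypeField(probs, np.ones((1, 2), bool), "normalized")
        from conftest import make_gm
        import pandas as pd
        from imap.genotype_io import TrioSet

        gm = make_gm(np.array([[0, 1], [0, 0], [0, 1]], dtype=np.int8), chroms=["1", "2"])
        trios = TrioSet(np.array([[0, 1, 2]]), np.ones((1, 2), bool))
        tab = joint_table(gm, trios, field, 0, 1, min_pair_trios=1)
        want_o = np.zeros((3, 3)); want_o[0, 1] = 1
        np.testing.assert_array_equal(tab.observed, want_o)
        want_e = np.zeros((3, 3)); want_e[0] = [0.5, 0.5, 0]
        np.testing.assert_allclose(tab.expected, want_e)

    def test_conservation_and_transpose_symmetry(self, rng):
        gm, ped = random_trio_dataset(
            rng, n_trios=30, n_markers=4, missing_rate=0.1, chroms=["1", "1", "2", "2"]
        )
        trios = extract_trios(gm, ped)
        field = normalized_expected_field(gm, trios)
        for a, b in [(0, 2), (0, 3), (1, 3)]:
            tab = joint_table(gm, trios, field, a, b, min_pair_trios=1)
            assert tab.observed.sum() == tab.n_pair
            assert tab.expected.sum() == pytest.approx(tab.n_pair, abs=1e-6)
            rev = joint_table(gm, trios, field, b, a, min_pair_trios=1)
            np.testing.assert_array_equal(rev.observed, tab.observed.T)
            s1 = imap_statistic(tab).statistic
            s2 = imap_statistic(rev).statistic
            assert s1 == pytest.approx(s2, rel=1e-12)

    def test_statistic_zero_iff_perfect_fit(self):
        o = np.array([[4, 0, 0], [0, 2, 0], [0, 0, 2]])
        tab = JointGenotypeTable(o, o.astype(float), 8, 0, 1)
        assert imap_statistic(tab).statistic == 0.0

    def test_two_discrepant_cells_sum(self):
        o = np.array([[2, 0, 0], [0, 1, 0], [0, 0, 1]])
        e = np.array([[1.0, 1.0, 0], [0, 1, 0], [0, 0, 1]])
        tab = JointGenotypeTable(o, e, 4, 0, 1)
        assert imap_statistic(tab).statistic == pytest.approx(2.0)

    def test_zero_expectation_with_observation_rejected(self):
        o = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]])
        e = np.array([[2.0, 0.0, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(ValueError):
            JointGenotypeTable(o, e, 4, 0, 1).validate()

    def test_min_pair_trios_enforced(self, rng):
        gm, ped = random_trio_dataset(rng, n_trios=3, n_markers=2, chroms=["1", "2"])
        trios = extract_trios(gm, ped)
        field = normalized_expected_field(gm, trios)
        with pytest.raises(InsufficientPairTrios):
            joint_table(gm, trios, field, 0, 1, min_pair_trios=50)

    def test_statistic_matches_cell_loop_oracle(self, rng):
        for _ in range(10):
            gm, ped = random_trio_dataset(rng, n_trios=25, n_markers=2, chroms=["1", "2"])
            trios = extract_trios(gm, ped)
            field = normalized_expected_field(gm, trios)
            tab = joint_table(gm, trios, field, 0, 1, min_pair_trios=1)
            want = oracles.chi2_like_score(tab.observed.tolist(), tab.expected.tolist())
            assert imap_statistic(tab).statistic == pytest.approx(want, abs=1e-12)


class TestAgainstBruteForce:
    def test_joint_table_and_score_match_enumeration(self, rng):
        """Full pipeline vs the independent scalar-loop oracle on random
        5-trio fixtures (the oracle recomputes correction and normalization
        from first principles)."""
        for rep in range(25):
            gm, ped = random_trio_dataset(
                rng, n_trios=5, n_markers=4, missing_rate=0.15, chroms=["1", "1", "2", "2"]
            )
            trios = extract_trios(gm, ped)
            field = normalized_expected_field(gm, trios)
            child = gm.genotypes[trios.child].tolist()
            father = gm.genotypes[trios.father].tolist()
            mother = gm.genotypes[trios.mother].tolist()
            usable = trios.usable.tolist()
            for a, b in [(0, 2), (1, 3)]:
                obs_o, exp_o, n_pair = oracles.pair_table(child, father, mother, usable, a, b)
                if n_pair == 0:
                    continue
                tab = joint_table(gm, trios, field, a, b, min_pair_trios=1)
                assert tab.n_pair == n_pair
                np.testing.assert_allclose(tab.observed, obs_o, atol=0)
                np.testing.assert_allclose(tab.expected, exp_o, atol=1e-12)
                want = oracles.chi2_like_score(obs_o, exp_o)
                assert score_pair(gm, trios, field, a, b, 1).statistic == pytest.approx(
                    want, abs=1e-12
                )


class TestScoreAllPairs:
    def test_matches_per_pair_computation(self, null_qc):
        gm, trios = null_qc
        field = normalized_expected_field(gm, trios)
        pairs = np.array([[0, 50], [3, 120], [40, 199 % gm.n_markers], [10, 170]])
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        df = score_all_pairs(gm, trios, field, pairs)
        for _, row in df.iterrows():
            want = score_pair(gm, trios, field, int(row.a), int(row.b)).statistic
            assert row.S == pytest.approx(want, rel=1e-10)

    def test_null_mean_score_consistent_with_pseudo_null(self, null_qc):
        """On interaction-free data the observed mean statistic across pairs
        sits within 3 standard errors of its own pseudo-control null mean."""
        from imap.null_inference import permutation_pvalue

        gm, trios = null_qc
        field = normalized_expected_field(gm, trios)
        rng = np.random.default_rng(5)
        chroms = gm.markers["chromosome"].to_numpy()
        obs, null = [], []
        for _ in range(40):
            a, b = sorted(rng.integers(0, gm.n_markers, 2))
            if a == b or chroms[a] == chroms[b]:
                continue
            res = permutation_pvalue(gm, trios, a, b, B=40, seed=5)
            obs.append(res.observed_S)
            null.extend(res.null_S)
        diff = np.mean(obs) - np.mean(null)
        se = np.sqrt(np.var(obs, ddof=1) / len(obs) + np.var(null, ddof=1) / len(null))
        assert abs(diff) < 3 * se
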