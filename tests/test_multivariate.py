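import itertools

import numpy as np
import pytest

from nestgrad.multivariate import (
    DistanceMatrix,
    jaccard_distance,
    mantel,
    morisita_horn_distance,
    pairwise_distances,
    permanova_oneway,
    permanova_twoway,
    ruzicka_distance,
)


class TestDistances:
    def test_jaccard_examples(self):
        assert jaccard_distance((1, 1, 1), (1, 1, 1)) == 0.0
        assert jaccard_distance((1, 1, 0), (0, 0, 1)) == 1.0
        assert jaccard_distance((1, 1, 1), (1, 1, 0)) == pytest.approx(1 / 3)

    def test_morisita_horn_examples(self):
        assert morisita_horn_distance((2, 4), (1, 2)) == pytest.approx(0.0)
        assert morisita_horn_distance((3, 0), (0, 5)) == pytest.approx(1.0)
        assert morisita_horn_distance((1, 1), (1, 3)) == pytest.approx(1 / 9)

    def test_ruzicka_examples(self):
        assert ruzicka_distance((2, 1), (2, 1)) == 0.0
        assert ruzicka_distance((2, 0), (0, 3)) == 1.0
        assert ruzicka_distance((3, 1, 0), (1, 1, 2)) == pytest.approx(2 / 3)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            jaccard_distance((0, 0), (0, 0))
        with pytest.raises(ValueError):
            morisita_horn_distance((0, 0), (1, 1))
        with pytest.raises(ValueError):
            ruzicka_distance((0, 0), (0, 0))

    def test_symmetry_and_range_random(self):
        rng = np.random.default_rng(0)
        for fn in (jaccard_distance, morisita_horn_distance, ruzicka_distance):
            for _ in range(30):
                x = rng.integers(0, 5, 8).astype(float)
                y = rng.integers(0, 5, 8).astype(float)
                if x.sum() == 0 or y.sum() == 0:
                    continue
                d = fn(x, y)
                assert 0.0 <= d <= 1.0
                assert fn(y, x) == pytest.approx(d)

    def test_pairwise_builder_validates(self):
        rng = np.random.default_rng(1)
        m = rng.integers(1, 5, size=(6, 4)).astype(float)
        d = pairwise_distances(m, metric="ruzicka", axis="columns")
        assert d.n == 4
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_agreement_with_scikit_bio(self):
        """Cross-check Jaccard against the independent scikit-bio/scipy route."""
        from scipy.spatial.distance import jaccard as scipy_jaccard

        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.random(10) < 0.5
            y = rng.random(10) < 0.5
            if not (x | y).any():
                continue
            assert jaccard_distance(x, y) == pytest.approx(
                float(scipy_jaccard(x, y))
            )


def _random_distance(n, rng):
    pts = rng.random((n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return d


class TestPermanovaOneway:
    def test_matches_scikit_bio_pseudo_f(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(3)
        d = _random_distance(12, rng)
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova_oneway(d, groups, n_perm=99, seed=0)
        theirs = skbio_permanova(SkbioDM(d), grouping=groups, permutations=99)
        assert ours.term("groups").pseudo_f == pytest.approx(
            float(theirs["test statistic"]), rel=1e-9
        )

    def test_exhaustive_p_equals_hand_enumeration(self):
        rng = np.random.default_rng(4)
        d = _random_distance(6, rng)
        groups = ["a", "a", "a", "b", "b", "b"]
        res = permanova_oneway(d, groups, n_perm="exhaustive")
        assert res.n_permutations == 20

        # independent enumeration with a from-scratch pseudo-F
        def hand_f(labels):
            labels = np.array(labels)
            d2 = d**2
            n = len(labels)
            sst = d2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for g in set(labels):
                idx = np.where(labels == g)[0]
                ssw += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
            return ((sst - ssw) / 1) / (ssw / 4)

        f_obs = hand_f(groups)
        perms = sorted(set(itertools.permutations(groups)))
        p_hand = sum(hand_f(p) >= f_obs for p in perms) / len(perms)
        assert res.term("groups").p == pytest.approx(p_hand)
        assert res.term("groups").pseudo_f == pytest.approx(f_obs)

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(5)
        d = _random_distance(9, rng)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        f1 = permanova_oneway(d, groups, n_perm=9, seed=0).term("groups").pseudo_f
        relabeled = ["x" if g == "b" else "y" if g == "a" else "z" for g in groups]
        f2 = permanova_oneway(d, relabeled, n_perm=9, seed=0).term("groups").pseudo_f
        perm = rng.permutation(9)
        f3 = (
            permanova_oneway(d[np.ix_(perm, perm)], [groups[i] for i in perm],
                             n_perm=9, seed=0)
            .term("groups").pseudo_f
        )
        assert f1 == pytest.approx(f2) == pytest.approx(f3)


class TestPermanovaTwoway:
    @staticmethod
    def _design(n_per_cell=5, effect_a=0.0, effect_b=0.0, interaction=0.0, seed=0):
        rng = np.random.default_rng(seed)
        labels_a, labels_b, pts = [], [], []
        for i, a in enumerate(["lo", "mid", "hi"]):
            for j, b in enumerate(["x", "y"]):
                for _ in range(n_per_cell):
                    mu = effect_a * i + effect_b * j + interaction * i * j
                    pts.append(rng.normal(mu, 1.0, size=3))
                    labels_a.append(a)
                    labels_b.append(b)
        pts = np.array(pts)
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return d, labels_a, labels_b

    def test_degrees_of_freedom_2x3_design(self):
        d, la, lb = self._design()
        res = permanova_twoway(d, la, lb, n_perm=9, seed=1)
        assert [t.df for t in res.terms] == [2, 1, 2]
        assert res.df_residual == 24

    def test_sums_of_squares_partition(self):
        d, la, lb = self._design(effect_a=1.0, effect_b=0.5, seed=3)
        res = permanova_twoway(d, la, lb, n_perm=9, seed=1)
        total = sum(t.ss for t in res.terms) + res.ss_residual
        assert total == pytest.approx(res.ss_total, rel=1e-9)

    def test_only_factor_a_structure(self):
        d, la, lb = self._design(effect_a=2.0, seed=7)
        res = permanova_twoway(d, la, lb, n_perm=199, seed=2)
        assert res.term("A").p <= 0.01
        assert res.term("B").p > 0.05
        assert res.term("A x B").p > 0.05

    def test_additive_factors_no_interaction(self):
        d, la, lb = self._design(effect_a=1.5, effect_b=1.5, seed=11)
        res = permanova_twoway(d, la, lb, n_perm=199, seed=3)
        assert res.term("A").p <= 0.05
        assert res.term("B").p <= 0.05
        assert res.term("A x B").p > 0.05

    def test_unbalanced_design_rejected(self):
        d, la, lb = self._design()
        with pytest.raises(ValueError, match="balanced"):
            permanova_twoway(d[:-1, :-1], la[:-1], lb[:-1], n_perm=9)


class TestMantel:
    def test_identical_matrices_r_is_one(self):
        rng = np.random.default_rng(8)
        d = _random_distance(6, rng)
        res = mantel(d, d.copy(), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exhaustive_p_equals_hand_enumeration(self):
        rng = np.random.default_rng(9)
        d1 = _random_distance(4, rng)
        d2 = _random_distance(4, rng)
        res = mantel(d1, d2, n_perm="exhaustive")
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(d1[iu], d2[iu])[0, 1]
        count = 0
        perms = list(itertools.permutations(range(4)))
        for p in perms:
            pm = d2[np.ix_(p, p)]
            count += abs(np.corrcoef(d1[iu], pm[iu])[0, 1]) >= abs(r_obs) - 1e-12
        assert res.p == pytest.approx(count / len(perms))
        assert res.r == pytest.approx(r_obs)

    def test_label_alignment(self):
        rng = np.random.default_rng(10)
        vals = _random_distance(5, rng)
        labels = ["a", "b", "c", "d", "e"]
        d1 = DistanceMatrix(labels, vals)
        order = [3, 1, 4, 0, 2]
        d2 = DistanceMatrix([labels[i] for i in order], vals[np.ix_(order, order)])
        res = mantel(d1, d2, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(11)
        d1 = _random_distance(6, rng)
        d2 = _random_distance(6, rng)
        r1 = mantel(d1, d2, n_perm=9, seed=0).r
        perm = rng.permutation(6)
        r2 = mantel(d1[np.ix_(perm, perm)], d2[np.ix_(perm, perm)], n_perm=9, seed=0).r
        assert r1 == pytest.approx(r2)

    def test_agreement_with_scikit_bio_r(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(12)
        d1 = _random_distance(7, rng)
        d2 = _random_distance(7, rng)
        r_skbio, _, _ = skbio_mantel(SkbioDM(d1), SkbioDM(d2), permutations=0)
        ours = mantel(d1, d2, n_perm=9, seed=0)
        assert ours.r == pytest.approx(float(r_skbio), rel=1e-9)
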