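import numpy as np
import pytest
from oracles import (
    auc_pair_counting,
    average_precision_hand,
    delong_p_permutation,
    kappa_closed_form,
    nsd_brute_force,
)

from ctanomaly import metrics as M


class TestRocAuc:
    def test_perfect_and_inverted_ranking(self):
        assert M.roc_auc([0.2, 0.8], [0, 1]) == 1.0
        assert M.roc_auc([0.8, 0.2], [0, 1]) == 0.0

    def test_partial_ranking_matches_pair_counting(self):
        # 3 concordant of 4 pairs
        assert M.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            M.roc_auc([0.1, 0.2], [1, 1])

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 50)
            scores = np.round(rng.random(n), 2)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert M.roc_auc(scores, labels) == pytest.approx(
                auc_pair_counting(scores, labels), abs=1e-12
            )

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert M.roc_auc(-scores, labels) == pytest.approx(
            1 - M.roc_auc(scores, labels)
        )


class TestPrAuc:
    def test_perfect_ranking(self):
        assert M.pr_auc([0.1, 0.9], [0, 1]) == 1.0

    def test_positive_ranked_second(self):
        assert M.pr_auc([0.9, 0.8], [0, 1]) == 0.5

    def test_matches_hand_summation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.sum() == 0:
                continue
            assert M.pr_auc(scores, labels) == pytest.approx(
                average_precision_hand(scores, labels)
            )

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(3)
        n, prevalence = 2000, 0.3
        labels = (rng.random(n) < prevalence).astype(int)
        scores = rng.random(n)
        assert M.pr_auc(scores, labels) == pytest.approx(labels.mean(), abs=0.05)


class TestConfusionMetrics:
    def test_perfect_separation(self):
        rep = M.confusion_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5)
        assert all(rep[k] == 1.0 for k in rep)

    def test_counted_example(self):
        # TP=1 FP=1 FN=0 TN=0 -> F1 = 2/(2+1) = 2/3
        rep = M.confusion_metrics([0.9, 0.8], [1, 0], 0.5)
        assert rep["f1"] == pytest.approx(2 / 3)

    def test_f1_zero_convention_without_positives(self):
        rep = M.confusion_metrics([0.1, 0.2], [0, 0], 0.5)
        assert rep["f1"] == 0.0


class TestKappa:
    def test_identical_raters(self):
        assert M.cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_perfectly_discordant(self):
        assert M.cohens_kappa([1, 0, 1, 0], [0, 1, 0, 1]) == -1.0

    def test_chance_level_agreement(self):
        assert M.cohens_kappa([1, 1, 0, 0], [1, 1, 1, 1]) == 0.0

    def test_matches_closed_form(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.integers(0, 2, 50)
            b = rng.integers(0, 2, 50)
            if (a == b).all() or a.std() == 0 or b.std() == 0:
                continue
            assert M.cohens_kappa(a, b) == pytest.approx(kappa_closed_form(a, b))


class TestBootstrap:
    def test_constant_statistic(self):
        lo, hi = M.bootstrap_ci(lambda d: 1.5, np.arange(20), B=50, seed=0)
        assert (lo, hi) == (1.5, 1.5)

    def test_deterministic_under_seed(self):
        data = np.random.default_rng(5).normal(size=50)
        a = M.bootstrap_ci(np.mean, data, B=200, seed=7)
        b = M.bootstrap_ci(np.mean, data, B=200, seed=7)
        assert a == b

    def test_mean_interval_width_matches_clt(self):
        data = np.random.default_rng(6).standard_normal(100)
        lo, hi = M.bootstrap_ci(np.mean, data, B=1000, seed=0)
        expected = 2 * 1.96 / np.sqrt(100)
        assert hi - lo == pytest.approx(expected, rel=0.2)

    def test_invalid_b(self):
        with pytest.raises(ValueError):
            M.bootstrap_ci(np.mean, [1, 2], B=0)


class TestDelong:
    def test_identical_models(self):
        scores = [0.1, 0.9, 0.4, 0.7]
        labels = [0, 1, 0, 1]
        a1, a2, z, p = M.delong_test(scores, scores, labels)
        assert a1 == a2
        assert z == 0.0
        assert p == 1.0

    def test_aucs_agree_with_roc_auc(self):
        rng = np.random.default_rng(7)
        s1, s2 = rng.random(40), rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        a1, a2, _, _ = M.delong_test(s1, s2, labels)
        assert a1 == pytest.approx(M.roc_auc(s1, labels))
        assert a2 == pytest.approx(M.roc_auc(s2, labels))

    def test_matches_pROC_reference_implementation(self):
        # cross-check the paired DeLong p-value against R's pROC package
        import subprocess

        rng = np.random.default_rng(21)
        rows = []
        for _ in range(5):
            n = 40
            labels = rng.integers(0, 2, n)
            labels[:4] = [0, 0, 1, 1]
            s1 = labels * rng.uniform(0.2, 0.8) + rng.normal(0, 1, n)
            s2 = labels * rng.uniform(0.2, 0.8) + rng.normal(0, 1, n)
            rows.append((labels, s1, s2))
        rcode_parts = ["suppressMessages(library(pROC))"]
        for i, (labels, s1, s2) in enumerate(rows):
            rcode_parts.append(
                f"l{i} <- c({','.join(map(str, labels))}); "
                f"a{i} <- c({','.join(f'{v:.10f}' for v in s1)}); "
                f"b{i} <- c({','.join(f'{v:.10f}' for v in s2)}); "
                f"t{i} <- roc.test(roc(l{i}, a{i}, quiet=TRUE, direction='<', levels=c(0,1)), "
                f"roc(l{i}, b{i}, quiet=TRUE, direction='<', levels=c(0,1)), "
                f"method='delong', paired=TRUE); "
                f"cat(sprintf('%.12f\\n', t{i}$p.value))"
            )
        out = subprocess.run(
            ["Rscript", "-e", "\n".join(rcode_parts)],
            capture_output=True,
            text=True,
            timeout=120,
        )
        assert out.returncode == 0, out.stderr
        reference = [float(v) for v in out.stdout.split()]
        for (labels, s1, s2), p_ref in zip(rows, reference):
            _, _, _, p = M.delong_test(s1, s2, labels)
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            labels = np.array([0] * 15 + [1] * 15)
            signal = labels * rng.uniform(0.2, 0.8)
            s1 = signal + rng.normal(0, 0.5, 30)
            s2 = signal + rng.normal(0, 0.5, 30)
            _, _, _, p = M.delong_test(s1, s2, labels)
            p_perm = delong_p_permutation(s1, s2, labels, n_rep=2000, seed=trial)
            assert p == pytest.approx(p_perm, abs=0.05)


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        assert M.dice(a, a) == 1.0
        assert M.dice(a, ~a) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0:2, :2, :2] = True  # 8 voxels each, 4 shared
        b[1:3, :2, :2] = True
        assert M.dice(a, b) == 0.5

    def test_both_empty(self):
        e = np.zeros((3, 3, 3), bool)
        assert M.dice(e, e) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.random((6, 6, 6)) > 0.5
        b = rng.random((6, 6, 6)) > 0.5
        assert M.dice(a, b) == M.dice(b, a)


class TestNsd:
    def test_identical_masks(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:6, 2:6, 2:6] = True
        assert M.nsd(m, m, 1.0) == 1.0

    def test_far_apart_cubes(self):
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros((12, 12, 12), bool)
        a[1, 1, 1] = True
        b[10, 10, 10] = True
        assert M.nsd(a, b, 1.0) == 0.0

    def test_one_voxel_translation_within_tolerance(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[2:5, 2:5, 2:5] = True
        b[3:6, 2:5, 2:5] = True
        assert M.nsd(a, b, 1.0, (1, 1, 1)) == 1.0

    def test_empty_mask_conventions(self):
        e = np.zeros((4, 4, 4), bool)
        m = e.copy()
        m[1, 1, 1] = True
        assert M.nsd(e, e, 1.0) == 1.0
        assert M.nsd(e, m, 1.0) == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        from scipy import ndimage

        for trial in range(10):
            a = np.zeros((12, 12, 12), bool)
            b = np.zeros((12, 12, 12), bool)
            ca = rng.integers(3, 9, 3)
            cb = ca + rng.integers(-2, 3, 3)
            grid = np.indices((12, 12, 12))
            a = ((grid - ca[:, None, None, None]) ** 2).sum(0) <= rng.integers(2, 9)
            b = ((grid - cb[:, None, None, None]) ** 2).sum(0) <= rng.integers(2, 9)
            spacing = (1.0, 1.0, 2.0)
            tol = float(rng.uniform(0.5, 2.5))
            assert M.nsd(a, b, tol, spacing) == pytest.approx(
                nsd_brute_force(a, b, tol, spacing), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        a = ndimage_ball((10, 10, 10), (4, 4, 4), 3.0)
        b = ndimage_ball((10, 10, 10), (6, 5, 5), 2.5)
        assert M.nsd(a, b, 1.5) == M.nsd(b, a, 1.5)


def ndimage_ball(shape, center, radius):
    grid = np.indices(shape)
    c = np.asarray(center)[:, None, None, None]
    return ((grid - c) ** 2).sum(0) <= radius**2


class TestClassificationReport:
    def test_cis_bracket_point_estimates(self):
        rng = np.random.default_rng(12)
        labels = rng.integers(0, 2, 120)
        labels[:2] = [0, 1]
        scores = np.clip(labels * 0.4 + rng.random(120) * 0.6, 0, 1)
        rep = M.classification_report(scores, labels, threshold=0.5, B=200, seed=0)
        for name in ("auc", "accuracy", "f1"):
            lo, hi = rep.ci[name]
            point = getattr(rep, name)
            assert lo <= point <= hi


# --- hypothesis property tests -------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 2**32 - 1))
def test_dice_and_nsd_symmetry_property(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((6, 6, 6)) > 0.6
    b = rng.random((6, 6, 6)) > 0.6
    assert M.dice(a, b) == M.dice(b, a)
    assert M.nsd(a, b, 1.0) == M.nsd(b, a, 1.0)


@settings(derandomize=True, max_examples=30)
@given(st.integers(0, 2**32 - 1))
def test_kappa_symmetry_and_bounds_property(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, 30)
    b = rng.integers(0, 2, 30)
    k = M.cohens_kappa(a, b)
    assert -1.0 <= k <= 1.0
    assert k == pytest.approx(M.cohens_kappa(b, a))
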