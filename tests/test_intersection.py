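"""Subspace-intersection estimators: SVD null space and explicit optimization."""

import numpy as np
import pytest

from conesect import (
    ChannelSet,
    ConvergenceError,
    DegeneracyError,
    DichromatCMF,
    SpectralAxis,
    UsageError,
    angular_error,
    derive_all_fundamentals,
    intersect_optim,
    intersect_pair,
    make_dichromat,
    make_fundamentals,
    make_observer_triple,
    resample,
)
from conesect.intersection import PAIR_FOR_CONE


def _remix(d: DichromatCMF, matrix: np.ndarray) -> DichromatCMF:
    """The same observer measured with different primaries."""
    return DichromatCMF(
        d.observer_class,
        ChannelSet(d.cmf.axis, d.cmf.values @ matrix, d.cmf.labels),
    )


class TestIntersectPairExact:
    def test_identity_mixings_recover_m_exactly(self, truth):
        protan = make_dichromat(truth, "protan", mixing=np.eye(2))  # [M, S]
        tritan = make_dichromat(truth, "tritan", mixing=np.eye(2))  # [L, M]
        r = intersect_pair(protan, tritan)
        assert r.cone == "M"
        assert angular_error(r.estimate_reported, truth.m) < 1e-10
        assert r.smallest_singular_value < 1e-12 * r.singular_values[0]

    def test_estimate_reported_conventions(self, noiseless_triple):
        r = intersect_pair(noiseless_triple["protan"], noiseless_triple["tritan"])
        assert np.max(np.abs(r.estimate_reported)) == pytest.approx(1.0)
        assert r.estimate_reported.sum() > 0

    def test_svd_coefficients_unit_norm(self, noiseless_triple):
        r = intersect_pair(noiseless_triple["deutan"], noiseless_triple["tritan"])
        combined = np.concatenate([r.x_first, r.x_second])
        assert np.linalg.norm(r.alpha * combined) == pytest.approx(1.0, abs=1e-12)

    def test_primary_invariance(self, truth):
        # remeasuring either observer with new (unknown) primaries leaves
        # the estimated ray unchanged
        rng = np.random.default_rng(99)
        obs = make_observer_triple(truth, seed=1)
        base = intersect_pair(obs["protan"], obs["tritan"])
        for _ in range(10):
            m1 = rng.uniform(-1, 1, (2, 2))
            m2 = rng.uniform(-1, 1, (2, 2))
            if min(abs(np.linalg.det(m1)), abs(np.linalg.det(m2))) < 0.05:
                continue
            r = intersect_pair(_remix(obs["protan"], m1), _remix(obs["tritan"], m2))
            assert angular_error(r.estimate_reported, base.estimate_reported) < 1e-8

    def test_scale_covariance(self, noiseless_triple):
        # scaling one observer's CMFs by c scales its coefficients by 1/c
        # relative to the other side (the joint unit-norm convention fixes
        # only the overall scale) and leaves the reported estimate unchanged
        first, second = noiseless_triple["protan"], noiseless_triple["deutan"]
        base = intersect_pair(first, second)
        scaled = intersect_pair(_remix(first, 10.0 * np.eye(2)), second)
        assert angular_error(
            scaled.estimate_reported, base.estimate_reported) < 1e-10
        rel_base = np.linalg.norm(base.x_first) / np.linalg.norm(base.x_second)
        rel_scaled = np.linalg.norm(scaled.x_first) / np.linalg.norm(scaled.x_second)
        assert rel_base / rel_scaled == pytest.approx(10.0, rel=1e-6)

    def test_argument_order_gives_same_ray(self, noiseless_triple):
        ab = intersect_pair(noiseless_triple["protan"], noiseless_triple["tritan"])
        ba = intersect_pair(noiseless_triple["tritan"], noiseless_triple["protan"])
        assert angular_error(ab.estimate_reported, ba.estimate_reported) < 1e-10


class TestIntersectPairContracts:
    def test_same_observer_class_rejected(self, truth):
        a = make_dichromat(truth, "protan", seed=1)
        b = make_dichromat(truth, "protan", seed=2)
        with pytest.raises(UsageError, match="protan"):
            intersect_pair(a, b)

    def test_duplicated_observer_planes_are_degenerate(self, truth):
        # relabelling a tritan as protan leaves two copies of one plane:
        # the null space is 2-D and no unique shared ray exists
        t = make_dichromat(truth, "tritan", mixing=np.array([[1.0, 0.2], [0.1, 1.0]]))
        fake_protan = DichromatCMF("protan", t.cmf)
        with pytest.raises(DegeneracyError, match="null space"):
            intersect_pair(fake_protan, t)

    def test_insufficient_axis_overlap_rejected(self, truth):
        narrow = SpectralAxis.from_range(500, 530, 5)
        a = make_dichromat(truth, "protan", seed=1)
        b = make_dichromat(truth, "tritan", seed=2)
        b_narrow = DichromatCMF("tritan", resample(b.cmf, narrow))
        with pytest.raises(UsageError, match="samples"):
            intersect_pair(a, b_narrow)

    def test_unknown_method_rejected(self, noiseless_triple):
        with pytest.raises(UsageError, match="method"):
            intersect_pair(
                noiseless_triple["protan"], noiseless_triple["tritan"],
                method="nullspace")


class TestIntersectPairNoisy:
    def test_one_sided_estimates_differ_under_noise(self, truth):
        obs = make_observer_triple(truth, noise_sd=0.01, seed=3)
        r = intersect_pair(obs["protan"], obs["tritan"])
        assert angular_error(r.estimate_first, r.estimate_second) > 1e-4
        assert angular_error(r.estimate_reported, truth.m) < 0.2

    def test_matches_gram_eigenvector_oracle(self, truth):
        # independent oracle: the constrained minimum-residual direction is
        # the eigenvector of the smallest eigenvalue of the 4x4 Gram matrix
        for seed in range(20):
            obs = make_observer_triple(truth, noise_sd=0.01, seed=seed)
            for cone, (a, b) in PAIR_FOR_CONE.items():
                r = intersect_pair(obs[a], obs[b])
                j = np.hstack([obs[a].cmf.values, -obs[b].cmf.values])
                _, vecs = np.linalg.eigh(j.T @ j)
                oracle = obs[a].cmf.values @ vecs[:2, 0]
                assert angular_error(r.estimate_reported, oracle) < 1e-10

    def test_median_error_increases_with_noise(self, truth):
        medians = []
        for sd in (1e-4, 1e-3, 1e-2):
            errs = [
                angular_error(
                    intersect_pair(o["protan"], o["tritan"]).estimate_reported,
                    truth.m,
                )
                for o in (
                    make_observer_triple(truth, noise_sd=sd, seed=s)
                    for s in range(60)
                )
            ]
            medians.append(float(np.median(errs)))
        assert medians[0] < medians[1] < medians[2]


class TestIntersectOptim:
    def test_agrees_with_svd_noiseless(self, noiseless_triple):
        for cone, (a, b) in PAIR_FOR_CONE.items():
            r_svd = intersect_pair(noiseless_triple[a], noiseless_triple[b])
            r_opt = intersect_optim(noiseless_triple[a], noiseless_triple[b])
            assert angular_error(
                r_opt.estimate_reported, r_svd.estimate_reported) < 1e-8

    def test_agrees_with_svd_noisy(self, truth):
        obs = make_observer_triple(truth, noise_sd=0.01, seed=17)
        r_svd = intersect_pair(obs["deutan"], obs["tritan"])
        r_opt = intersect_optim(obs["deutan"], obs["tritan"])
        assert angular_error(r_opt.estimate_reported, r_svd.estimate_reported) < 1e-8

    def test_nonneg_inactive_on_noiseless_data(self, noiseless_triple):
        r_svd = intersect_pair(noiseless_triple["protan"], noiseless_triple["tritan"])
        r_nn = intersect_optim(
            noiseless_triple["protan"], noiseless_triple["tritan"], nonneg=True)
        assert angular_error(r_nn.estimate_reported, r_svd.estimate_reported) < 1e-8
        assert r_nn.estimate_reported.min() >= -1e-12

    def test_nonneg_removes_negative_lobe(self, truth):
        # adversarial smooth perturbation: a bump where the shared
        # fundamental vanishes drives the unconstrained estimate negative;
        # the constrained one must stay (numerically) non-negative
        obs = make_observer_triple(truth, noise_sd=0.0, seed=2)
        wl = truth.axis.wavelengths
        lobe = np.exp(-0.5 * ((wl - 700.0) / 20.0) ** 2)
        perturbed = obs["protan"].cmf.values + np.outer(lobe, [-0.08, -0.05])
        p_adv = DichromatCMF(
            "protan", ChannelSet(truth.axis, perturbed, obs["protan"].cmf.labels))
        r_svd = intersect_pair(p_adv, obs["tritan"])
        r_nn = intersect_optim(p_adv, obs["tritan"], nonneg=True)
        assert r_svd.estimate_reported.min() < 0
        assert r_nn.estimate_reported.min() >= -1e-12

    def test_nonneg_infeasible_with_dense_noise_raises(self, truth):
        # i.i.d. noise at wavelengths where the matching functions vanish
        # rules out every direction: the hard constraint set is empty
        obs = make_observer_triple(truth, noise_sd=0.02, seed=5)
        with pytest.raises(ConvergenceError, match="infeasible"):
            intersect_optim(obs["protan"], obs["tritan"], nonneg=True)


class TestDeriveAllFundamentals:
    def test_noiseless_triple_recovers_truth(self, truth, noiseless_triple):
        derived = derive_all_fundamentals(**noiseless_triple)
        for cone in "LMS":
            err = angular_error(
                derived[cone].estimate_reported, truth.channel(cone))
            assert err < 1e-8
        diag = derived.diagnostics
        assert set(diag) == {"L", "M", "S"}
        assert all(d["singular_value_ratio"] < 1e-12 for d in diag.values())

    def test_pair_assignment(self, noiseless_triple):
        derived = derive_all_fundamentals(**noiseless_triple)
        assert derived["L"].observer_pair == ("deutan", "tritan")
        assert derived["M"].observer_pair == ("protan", "tritan")
        assert derived["S"].observer_pair == ("protan", "deutan")

    def test_narrow_tritan_range_restricts_l_and_m_only(self, truth, noiseless_triple):
        narrow = SpectralAxis.from_range(400, 650, 5)
        tritan = DichromatCMF(
            "tritan", resample(noiseless_triple["tritan"].cmf, narrow))
        derived = derive_all_fundamentals(
            noiseless_triple["protan"], noiseless_triple["deutan"], tritan)
        assert derived["L"].axis == narrow
        assert derived["M"].axis == narrow
        assert derived["S"].axis == truth.axis

    def test_as_cone_fundamentals_on_common_axis(self, truth, noiseless_triple):
        f = derive_all_fundamentals(**noiseless_triple).as_cone_fundamentals()
        assert f.axis == truth.axis
        assert np.allclose(f.values, truth.values, atol=1e-8)

    def test_mislabelled_argument_rejected(self, noiseless_triple):
        with pytest.raises(UsageError, match="holds"):
            derive_all_fundamentals(
                noiseless_triple["deutan"], noiseless_triple["protan"],
                noiseless_triple["tritan"])

    def test_pairwise_failure_names_the_pair(self, truth, noiseless_triple):
        # duplicate plane between protan and deutan poisons only S
        d = make_dichromat(truth, "protan", mixing=np.eye(2))
        fake_deutan = DichromatCMF("deutan", d.cmf)
        with pytest.raises(DegeneracyError, match=r"S-cone.*protan.*deutan"):
            derive_all_fundamentals(d, fake_deutan, noiseless_triple["tritan"])

    def test_exact_recovery_over_many_seeds(self, truth):
        worst = 0.0
        for seed in range(30):
            obs = make_observer_triple(truth, noise_sd=0.0, seed=seed)
            derived = derive_all_fundamentals(**obs)
            for cone in "LMS":
                worst = max(worst, angular_error(
                    derived[cone].estimate_reported, truth.channel(cone)))
        assert worst < 1e-6
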