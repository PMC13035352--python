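import numpy as np
import pytest

from airdmd import (
    align_models,
    apply_signed_permutation,
    build_pair,
    drop_trailing_low_energy,
    fit,
    generate_flow_snapshots,
    interpolate,
    interpolation_weight,
    mean_relative_error,
    reconstruct_deck,
    reconstruct_interpolated,
    snapshot_errors,
)
from airdmd.dmd import DMDModel, _eig_sorted
from airdmd.errors import CoverageError, DataError, ExtrapolationError


def make_model(A_tilde, r=None, n_rows=6, dt=1.0, parameter=None, seed=0):
    """Fabricate a structurally consistent model around a prescribed
    reduced operator (identity-aligned basis)."""
    A_tilde = np.asarray(A_tilde, dtype=float)
    r = r or A_tilde.shape[0]
    rng = np.random.default_rng(seed)
    Ur = np.eye(n_rows)[:, :r]
    lam, W = _eig_sorted(A_tilde)
    Phi = Ur.astype(complex) @ W
    b0 = rng.standard_normal(r).astype(complex)
    x1 = (Phi @ b0).real
    return DMDModel(
        Ur=Ur,
        Sr=np.ones(r),
        Vr=np.eye(r + 3, r),
        A_tilde=A_tilde,
        Lambda=lam,
        W=W,
        Phi=Phi,
        b0=b0,
        x1=x1,
        dt=dt,
        r=r,
        parameter=parameter,
    )


class TestWeight:
    def test_midpoint(self):
        assert interpolation_weight(55, 50, 60) == pytest.approx(0.5)

    def test_lower_endpoint(self):
        assert interpolation_weight(50, 50, 60) == pytest.approx(1.0)

    def test_upper_endpoint(self):
        assert interpolation_weight(60, 50, 60) == pytest.approx(0.0)

    def test_extrapolation_refused(self):
        with pytest.raises(ExtrapolationError):
            interpolation_weight(70, 50, 60)

    def test_extrapolation_override(self):
        assert interpolation_weight(70, 50, 60, allow_extrapolation=True) == pytest.approx(-1.0)

    def test_equal_rates_rejected(self):
        with pytest.raises(DataError):
            interpolation_weight(50, 50, 50)


class TestAlign:
    def test_identical_models_unchanged(self, trained_models):
        m1 = trained_models[40.0]
        aligned = align_models(m1, m1)
        assert aligned is m1

    def test_negated_columns_restored(self, trained_models):
        m1 = trained_models[40.0]
        m2 = trained_models[60.0]
        flipped = apply_signed_permutation(
            m2, np.arange(m2.r), -np.ones(m2.r)
        )
        aligned = align_models(m1, flipped)
        signs = np.sign(np.einsum("ij,ij->j", m1.Ur, aligned.Ur))
        assert np.all(signs == 1.0)

    def test_swapped_columns_restored(self, trained_models):
        m1 = trained_models[40.0]
        m2 = trained_models[60.0]
        perm = np.array([1, 0, 3, 2])
        swapped = apply_signed_permutation(m2, perm, np.ones(m2.r))
        aligned = align_models(m1, swapped)
        # brute-force optimum over all column permutations
        import itertools

        corr = np.abs(m1.Ur.T @ swapped.Ur)
        best = max(
            itertools.permutations(range(m2.r)),
            key=lambda p: sum(corr[i, p[i]] for i in range(m2.r)),
        )
        np.testing.assert_allclose(np.abs(aligned.Ur), np.abs(swapped.Ur[:, list(best)]))

    def test_idempotent(self, trained_models):
        m1 = trained_models[40.0]
        m2 = apply_signed_permutation(
            trained_models[60.0], np.array([2, 0, 1, 3]), np.array([-1.0, 1.0, -1.0, 1.0])
        )
        once = align_models(m1, m2)
        twice = align_models(m1, once)
        np.testing.assert_array_equal(once.Ur, twice.Ur)

    def test_perturbation_preserves_reconstruction(self, trained_models, deck50):
        m2 = trained_models[60.0]
        perturbed = apply_signed_permutation(
            m2, np.array([3, 1, 0, 2]), np.array([1.0, -1.0, -1.0, 1.0])
        )
        a = reconstruct_deck(m2, deck50.times)
        b = reconstruct_deck(perturbed, deck50.times)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_mismatched_rank_rejected(self, trained_models, deck50):
        m1 = trained_models[40.0]
        small = fit(build_pair(deck50), rank=2)
        with pytest.raises(DataError):
            align_models(m1, small)


class TestInterpolate:
    def test_endpoint_operator_identity(self, trained_models):
        pset = interpolate(trained_models, 40.0)
        np.testing.assert_allclose(
            pset.A_theta, trained_models[40.0].A_tilde, atol=1e-12
        )
        assert pset.theta == pytest.approx(1.0)

    def test_scaled_identity_blend(self):
        c1, c2 = 0.9, 0.5
        models = {
            1.0: make_model(c1 * np.eye(3), parameter=1.0),
            2.0: make_model(c2 * np.eye(3), parameter=2.0),
        }
        pset = interpolate(models, 1.5)
        np.testing.assert_allclose(pset.Lambda_theta, 0.5 * (c1 + c2) * np.ones(3), atol=1e-12)

    def test_commuting_diagonal_blend(self):
        d1 = np.diag([0.9, 0.4])
        d2 = np.diag([0.8, 0.6])
        models = {0.0: make_model(d1), 1.0: make_model(d2)}
        pset = interpolate(models, 0.25)
        theta = pset.theta  # weight on the lower rate: 0.75
        assert theta == pytest.approx(0.75)
        want = theta * np.diag(d1) + (1 - theta) * np.diag(d2)
        np.testing.assert_allclose(np.sort(pset.Lambda_theta.real), np.sort(want), atol=1e-12)

    def test_weight_affinity(self, trained_models):
        A1 = trained_models[40.0].A_tilde
        aligned2 = align_models(trained_models[40.0], trained_models[60.0])
        A2 = aligned2.A_tilde
        for vdot in (40.0, 45.0, 50.0, 55.0, 60.0):
            pset = interpolate(trained_models, vdot)
            np.testing.assert_allclose(
                pset.A_theta,
                pset.theta * A1 + (1 - pset.theta) * A2,
                atol=1e-12,
            )

    def test_no_bracket_raises(self, trained_models):
        with pytest.raises(CoverageError):
            interpolate(trained_models, 70.0)

    def test_single_model_raises(self, trained_models):
        with pytest.raises(CoverageError):
            interpolate({40.0: trained_models[40.0]}, 40.0)

    def test_re_orthonormalize_flag(self, trained_models):
        pset = interpolate(trained_models, 50.0, re_orthonormalize=True)
        gram = pset.U_theta.T @ pset.U_theta
        np.testing.assert_allclose(gram, np.eye(pset.r), atol=1e-10)


class TestReconstructInterpolated:
    def test_endpoint_matches_trained_model(self, trained_models, deck50):
        pset = interpolate(trained_models, 40.0)
        a = reconstruct_interpolated(pset, deck50.times)
        b = reconstruct_deck(trained_models[40.0], deck50.times)
        rel = np.linalg.norm(a.values - b.values) / np.linalg.norm(b.values)
        assert rel < 1e-8

    def test_endpoint_invariant_to_sign_flips(self, trained_models, deck50):
        base = reconstruct_deck(trained_models[40.0], deck50.times)
        for signs in ([-1, 1, 1, 1], [-1, -1, -1, -1], [1, -1, 1, -1]):
            flipped = apply_signed_permutation(
                trained_models[60.0], np.arange(4), np.array(signs, dtype=float)
            )
            pset = interpolate({40.0: trained_models[40.0], 60.0: flipped}, 40.0)
            rec = reconstruct_interpolated(pset, deck50.times)
            rel = np.linalg.norm(rec.values - base.values) / np.linalg.norm(base.values)
            assert rel < 1e-8

    def test_midpoint_recovers_held_out_deck(self, trained_models, deck50):
        pset = interpolate(trained_models, 50.0)
        rec = reconstruct_interpolated(pset, deck50.times)
        mre = mean_relative_error(snapshot_errors(deck50, rec))
        assert mre <= 5.0
        for v in (40.0, 60.0):
            reuse = reconstruct_deck(trained_models[v], deck50.times)
            assert mre < mean_relative_error(snapshot_errors(deck50, reuse))

    def test_single_instant_zero(self, trained_models):
        pset = interpolate(trained_models, 50.0)
        deck = reconstruct_interpolated(pset, np.array([0.0]))
        want = (pset.Phi_theta @ pset.b0_theta).real
        np.testing.assert_allclose(deck.values.reshape(-1), want, atol=1e-12)
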