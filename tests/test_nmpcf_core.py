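"""Co-factorization core: KL divergence, update rules, renormalization, fit.

The single-step update tests compare the implementation against a
brute-force oracle that evaluates the multiplicative rules with explicit
elementwise loops — an independent arithmetic path.
"""

import numpy as np
import pytest

from wheezesep import (
    FactorModel,
    HyperParams,
    SegmentSet,
    WeightScheme,
    kl_divergence,
    objective,
    reconstruct_segment,
    renormalize_model,
)
from wheezesep.nmpcf_core import (
    fit,
    init_model,
    update_activations,
    update_shared_basis,
    update_wheeze_basis,
)

from conftest import random_segments


# ---------------------------------------------------------------------------
# brute-force oracle: literal loop evaluation of the update rules


def oracle_xhat(m, segs, l):
    f, t = segs.segments[l].shape
    out = np.zeros((f, t))
    for i in range(f):
        for j in range(t):
            for k in range(m.u_r.shape[1]):
                out[i, j] += m.u_r[i, k] * m.d_xr[l][k] * m.v_r[l][k, j]
            for k in range(m.u_w[l].shape[1]):
                out[i, j] += m.u_w[l][i, k] * m.d_xw[l][k] * m.v_w[l][k, j]
    return out


def oracle_yhat(m, t_y):
    f = m.u_r.shape[0]
    out = np.zeros((f, t_y))
    for i in range(f):
        for j in range(t_y):
            for k in range(m.u_r.shape[1]):
                out[i, j] += m.u_r[i, k] * m.d_yr[k] * m.h_r[k, j]
    return out


def oracle_update_u_r(m, segs, y, w, eps=1e-12):
    L = len(segs)
    f, k_r = m.u_r.shape
    new = np.zeros((f, k_r))
    for i in range(f):
        for k in range(k_r):
            num = 0.0
            den = (2 * L + 2) * m.u_r[i, k]
            for l in range(L):
                lam = w.lambda_r1 if segs.labels[l] else w.lambda_r0
                xhat = oracle_xhat(m, segs, l)
                for j in range(segs.segments[l].shape[1]):
                    ratio = segs.segments[l][i, j] / max(xhat[i, j], eps)
                    num += lam * ratio * m.d_xr[l][k] * m.v_r[l][k, j]
                    den += lam * m.d_xr[l][k] * m.v_r[l][k, j]
            if y is not None and w.alpha > 0:
                yhat = oracle_yhat(m, y.shape[1])
                for j in range(y.shape[1]):
                    ratio = y[i, j] / max(yhat[i, j], eps)
                    num += w.alpha * ratio * m.d_yr[k] * m.h_r[k, j]
                    den += w.alpha * m.d_yr[k] * m.h_r[k, j]
            new[i, k] = m.u_r[i, k] * num / max(den, eps)
    return new


def oracle_update_u_w(m, segs, w, l, eps=1e-12):
    f, k_w = m.u_w[l].shape
    new = np.zeros((f, k_w))
    xhat = oracle_xhat(m, segs, l)
    for i in range(f):
        for k in range(k_w):
            num, den = 0.0, 2 * m.u_w[l][i, k]
            for j in range(segs.segments[l].shape[1]):
                ratio = segs.segments[l][i, j] / max(xhat[i, j], eps)
                num += w.lambda_w * ratio * m.d_xw[l][k] * m.v_w[l][k, j]
                den += w.lambda_w * m.d_xw[l][k] * m.v_w[l][k, j]
            new[i, k] = m.u_w[l][i, k] * num / max(den, eps)
    return new


def oracle_update_v(m, segs, l, which, eps=1e-12):
    """Literal activation rule for V_R(l) or V_W(l) at the current state."""
    u = m.u_r if which == "r" else m.u_w[l]
    d = m.d_xr[l] if which == "r" else m.d_xw[l]
    v = m.v_r[l] if which == "r" else m.v_w[l]
    xhat = oracle_xhat(m, segs, l)
    new = np.zeros_like(v)
    for k in range(v.shape[0]):
        for j in range(v.shape[1]):
            num, den = 0.0, 0.0
            for i in range(u.shape[0]):
                ratio = segs.segments[l][i, j] / max(xhat[i, j], eps)
                num += u[i, k] * d[k] * ratio
                den += u[i, k] * d[k]
            new[k, j] = v[k, j] * num / max(den, eps)
    return new


def oracle_update_h_r(m, y, eps=1e-12):
    yhat = oracle_yhat(m, y.shape[1])
    new = np.zeros_like(m.h_r)
    for k in range(m.h_r.shape[0]):
        for j in range(m.h_r.shape[1]):
            num, den = 0.0, 0.0
            for i in range(m.u_r.shape[0]):
                ratio = y[i, j] / max(yhat[i, j], eps)
                num += m.u_r[i, k] * m.d_yr[k] * ratio
                den += m.u_r[i, k] * m.d_yr[k]
            new[k, j] = m.h_r[k, j] * num / max(den, eps)
    return new


def oracle_objective(m, segs, y, w):
    total = 0.0
    L = len(segs)
    for l in range(L):
        lam = w.lambda_r1 if segs.labels[l] else w.lambda_r0
        x, xhat = segs.segments[l], oracle_xhat(m, segs, l)
        for i in range(x.shape[0]):
            for j in range(x.shape[1]):
                if x[i, j] > 0:
                    total += lam * (x[i, j] * np.log(x[i, j] / xhat[i, j]) - x[i, j] + xhat[i, j])
                else:
                    total += lam * xhat[i, j]
        total += float(np.sum(m.u_w[l] ** 2))
    total += (L + 1) * float(np.sum(m.u_r**2))
    if y is not None and w.alpha > 0:
        yhat = oracle_yhat(m, y.shape[1])
        for i in range(y.shape[0]):
            for j in range(y.shape[1]):
                if y[i, j] > 0:
                    total += w.alpha * (y[i, j] * np.log(y[i, j] / yhat[i, j]) - y[i, j] + yhat[i, j])
                else:
                    total += w.alpha * yhat[i, j]
    return total


def make_model(rng, f, k_r, k_w, lengths, t_y=None):
    model = FactorModel(
        u_r=rng.uniform(0.1, 1, (f, k_r)),
        u_w=[rng.uniform(0.1, 1, (f, k_w)) for _ in lengths],
        v_r=[rng.uniform(0.1, 1, (k_r, t)) for t in lengths],
        v_w=[rng.uniform(0.1, 1, (k_w, t)) for t in lengths],
        d_xr=[rng.uniform(0.5, 2, k_r) for _ in lengths],
        d_xw=[rng.uniform(0.5, 2, k_w) for _ in lengths],
    )
    if t_y:
        model.h_r = rng.uniform(0.1, 1, (k_r, t_y))
        model.d_yr = rng.uniform(0.5, 2, k_r)
    return model


# ---------------------------------------------------------------------------


class TestKlDivergence:
    def test_identity_is_zero(self, rng):
        x = rng.uniform(0, 5, (4, 3))
        assert kl_divergence(x, x) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "x, xhat, expected",
        [
            ([[2.0]], [[1.0]], 2 * np.log(2) - 1),  # scalar evaluation
            ([[0.0]], [[1.0]], 1.0),  # 0*log(0) convention
            ([[1.0]], [[2.0]], np.log(0.5) + 1),
        ],
    )
    def test_scalar_values(self, x, xhat, expected):
        assert kl_divergence(np.array(x), np.array(xhat)) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.array([[-1.0]]), np.array([[1.0]]))

    def test_nonnegative_for_random_pairs(self, rng):
        for _ in range(50):
            x = rng.uniform(0, 3, (3, 4))
            xhat = rng.uniform(0.1, 3, (3, 4))
            assert kl_divergence(x, xhat) >= -1e-12


class TestReconstruction:
    def test_zero_activations_zero_output(self, rng):
        m = make_model(rng, 3, 2, 2, [4])
        m.v_r[0][:] = 0
        m.v_w[0][:] = 0
        xr, xw = reconstruct_segment(m, 0)
        assert np.all(xr == 0) and np.all(xw == 0)

    def test_scalar_case(self):
        m = FactorModel(
            u_r=np.array([[2.0]]), u_w=[np.array([[0.0]])],
            v_r=[np.array([[4.0]])], v_w=[np.array([[0.0]])],
            d_xr=[np.array([3.0])], d_xw=[np.array([1.0])],
        )
        xr, _ = reconstruct_segment(m, 0)
        assert xr[0, 0] == pytest.approx(24.0)

    def test_matches_loop_oracle(self, rng):
        m = make_model(rng, 4, 3, 2, [5, 3])
        segs = random_segments(rng, f=4, lengths=(5, 3))
        for l in range(2):
            xr, xw = reconstruct_segment(m, l)
            np.testing.assert_allclose(xr + xw, oracle_xhat(m, segs, l), rtol=1e-12)


class TestObjective:
    def test_matches_brute_force(self, rng):
        segs = random_segments(rng, f=2, lengths=(2, 2), labels=(1, 0))
        m = make_model(rng, 2, 1, 1, [2, 2], t_y=2)
        y = rng.uniform(0.1, 2, (2, 2))
        w = WeightScheme()
        assert objective(m, segs, y, w) == pytest.approx(
            oracle_objective(m, segs, y, w), rel=1e-12
        )

    def test_perfect_fit_leaves_only_penalties(self, rng):
        segs = random_segments(rng, f=3, lengths=(4,), labels=(0,))
        m = make_model(rng, 3, 2, 2, [4], t_y=3)
        xr, xw = reconstruct_segment(m, 0)
        segs.segments[0] = xr + xw  # Xhat == X exactly
        y = (m.u_r * m.d_yr) @ m.h_r
        w = WeightScheme()
        expected = 2 * np.sum(m.u_r**2) + np.sum(m.u_w[0] ** 2)
        assert objective(m, segs, y, w) == pytest.approx(expected, rel=1e-10)

    def test_linear_in_segment_weight(self, rng):
        segs = random_segments(rng, f=3, lengths=(4, 4), labels=(0, 0))
        m = make_model(rng, 3, 2, 2, [4, 4])
        w1 = WeightScheme(lambda_r0=1.0, lambda_r1=1.0, lambda_w=0.5, alpha=0.0)
        w2 = WeightScheme(lambda_r0=2.0, lambda_r1=2.0, lambda_w=0.5, alpha=0.0)
        pen = 3 * np.sum(m.u_r**2) + sum(np.sum(u**2) for u in m.u_w)
        fit1 = objective(m, segs, None, w1) - pen
        fit2 = objective(m, segs, None, w2) - pen
        assert fit2 == pytest.approx(2 * fit1, rel=1e-10)

    def test_alpha_without_y_rejected(self, rng):
        segs = random_segments(rng, f=3, lengths=(4,), labels=(0,))
        m = make_model(rng, 3, 2, 2, [4])
        with pytest.raises(ValueError):
            objective(m, segs, None, WeightScheme())


class TestSingleStepUpdates:
    """Implementation vs literal loop oracle, scalar and 2x2 instances."""

    @pytest.mark.parametrize("f,k_r,k_w,lengths,labels,t_y", [
        (1, 1, 1, (1,), (0,), 1),          # scalar
        (2, 1, 1, (2, 2), (1, 0), 2),      # 2x2, two segments
        (2, 2, 2, (2,), (1,), 2),          # 2x2 with rank 2
    ])
    def test_updates_match_oracle(self, rng, f, k_r, k_w, lengths, labels, t_y):
        segs = random_segments(rng, f=f, lengths=lengths, labels=labels)
        y = rng.uniform(0.1, 2, (f, t_y))
        w = WeightScheme(lambda_r0=1.7, lambda_r1=0.3, lambda_w=0.25, alpha=0.8)

        m = make_model(rng, f, k_r, k_w, lengths, t_y=t_y)
        expected_ur = oracle_update_u_r(m.copy(), segs, y, w)
        got_ur = update_shared_basis(m, segs, y, w)
        np.testing.assert_allclose(got_ur, expected_ur, rtol=1e-12)

        for l in range(len(lengths)):
            expected_uw = oracle_update_u_w(m.copy(), segs, w, l)
            got_uw = update_wheeze_basis(m, segs, w, l)
            np.testing.assert_allclose(got_uw, expected_uw, rtol=1e-12)

        # activations: the implementation updates V_R then V_W (refreshing
        # Xhat in between) then H_R; the oracle replays that sequence with
        # literal loops
        mo = m.copy()
        expected = {}
        for l in range(len(lengths)):
            expected[("vr", l)] = oracle_update_v(mo, segs, l, "r")
            mo.v_r[l] = expected[("vr", l)]
            expected[("vw", l)] = oracle_update_v(mo, segs, l, "w")
            mo.v_w[l] = expected[("vw", l)]
        expected["hr"] = oracle_update_h_r(mo, y)
        update_activations(m, segs, y)
        for l in range(len(lengths)):
            np.testing.assert_allclose(m.v_r[l], expected[("vr", l)], rtol=1e-12)
            np.testing.assert_allclose(m.v_w[l], expected[("vw", l)], rtol=1e-12)
        np.testing.assert_allclose(m.h_r, expected["hr"], rtol=1e-12)

    def test_zero_basis_column_stays_zero(self, rng):
        segs = random_segments(rng, f=3, lengths=(4,), labels=(0,))
        m = make_model(rng, 3, 2, 2, [4], t_y=3)
        m.u_r[:, 0] = 0.0
        y = rng.uniform(0.1, 2, (3, 3))
        update_shared_basis(m, segs, y, WeightScheme())
        assert np.all(m.u_r[:, 0] == 0)

    def test_perfect_reconstruction_is_activation_fixed_point(self, rng):
        m = make_model(rng, 3, 2, 2, [4])
        xr, xw = reconstruct_segment(m, 0)
        segs = SegmentSet(segments=[xr + xw], labels=[0])
        v_r_before = m.v_r[0].copy()
        v_w_before = m.v_w[0].copy()
        update_activations(m, segs, None, alpha=0.0)
        np.testing.assert_allclose(m.v_r[0], v_r_before, rtol=1e-10)
        np.testing.assert_allclose(m.v_w[0], v_w_before, rtol=1e-10)

    def test_lambda_w_zero_shrinks_wheeze_basis(self, rng):
        segs = random_segments(rng, f=3, lengths=(4,), labels=(0,))
        m = make_model(rng, 3, 2, 2, [4])
        w = WeightScheme(lambda_r0=1.0, lambda_r1=1.0, lambda_w=0.0, alpha=0.0)
        norms = [np.linalg.norm(m.u_w[0])]
        for _ in range(5):
            update_wheeze_basis(m, segs, w, 0)
            norms.append(np.linalg.norm(m.u_w[0]))
        assert all(b <= a for a, b in zip(norms, norms[1:]))

    def test_nonnegativity_preserved(self, rng):
        w = WeightScheme()
        for trial in range(20):
            segs = random_segments(rng, f=4, lengths=(5, 3), labels=(0, 1))
            m = make_model(rng, 4, 2, 2, [5, 3], t_y=4)
            y = rng.uniform(0, 2, (4, 4))
            update_shared_basis(m, segs, y, w)
            update_wheeze_basis(m, segs, w, 0)
            update_wheeze_basis(m, segs, w, 1)
            update_activations(m, segs, y)
            for arr in [m.u_r, *m.u_w, *m.v_r, *m.v_w, m.h_r]:
                assert np.all(arr >= 0)


class TestRenormalization:
    def test_column_example(self):
        m = FactorModel(
            u_r=np.array([[3.0], [4.0]]), u_w=[np.array([[1.0], [0.0]])],
            v_r=[np.array([[1.0]])], v_w=[np.array([[1.0]])],
            d_xr=[np.array([2.0])], d_xw=[np.array([1.0])],
        )
        renormalize_model(m)
        np.testing.assert_allclose(m.u_r[:, 0], [0.6, 0.8])
        # gain absorbed 5 from the basis column (activation already unit)
        assert m.d_xr[0][0] == pytest.approx(10.0)

    def test_already_normalized_unchanged(self, rng):
        m = make_model(rng, 4, 2, 2, [3])
        renormalize_model(m)
        snapshot = m.copy()
        renormalize_model(m)
        np.testing.assert_allclose(m.u_r, snapshot.u_r, rtol=1e-12)
        np.testing.assert_allclose(m.d_xr[0], snapshot.d_xr[0], rtol=1e-12)

    def test_reconstruction_invariant(self, rng):
        m = make_model(rng, 5, 3, 2, [4, 6], t_y=5)
        before = [np.sum(reconstruct_segment(m, l), axis=0) for l in range(2)]
        y_before = (m.u_r * m.d_yr) @ m.h_r
        renormalize_model(m)
        for l in range(2):
            after = np.sum(reconstruct_segment(m, l), axis=0)
            np.testing.assert_allclose(after, before[l], atol=1e-10)
        y_after = (m.u_r * m.d_yr) @ m.h_r
        np.testing.assert_allclose(y_after, y_before, atol=1e-10)

    def test_unit_norms_after(self, rng):
        m = make_model(rng, 4, 3, 2, [5], t_y=4)
        renormalize_model(m)
        np.testing.assert_allclose(np.linalg.norm(m.u_r, axis=0), 1.0)
        np.testing.assert_allclose(np.linalg.norm(m.v_r[0], axis=1), 1.0)
        np.testing.assert_allclose(np.linalg.norm(m.h_r, axis=1), 1.0)

    def test_zero_column_left_as_zero(self, rng):
        m = make_model(rng, 4, 2, 2, [3])
        m.u_r[:, 1] = 0.0
        renormalize_model(m)
        assert np.all(m.u_r[:, 1] == 0)
        assert m.d_xr[0][1] == 0.0


class TestFit:
    def test_zero_iterations_returns_initialization(self, small_segments, default_weights):
        hp = HyperParams(k_r=3, k_w=2, max_iter=0, seed=7)
        model, trace = fit(small_segments, y=None,
                           hp=hp, w=WeightScheme(alpha=0.0))
        ref = init_model(small_segments, hp, with_training=False)
        np.testing.assert_array_equal(model.u_r, ref.u_r)
        assert len(trace) == 1

    def test_equal_seeds_identical_traces(self, rng, small_hp, default_weights):
        segs = random_segments(rng, f=6, lengths=(8, 6))
        y = rng.uniform(0, 2, (6, 10))
        _, t1 = fit(segs, y, small_hp, default_weights)
        _, t2 = fit(segs, y, small_hp, default_weights)
        np.testing.assert_array_equal(t1, t2)

    def test_trace_length(self, small_segments, small_hp, rng):
        y = rng.uniform(0, 2, (5, 8))
        _, trace = fit(small_segments, y, small_hp, WeightScheme())
        assert len(trace) == small_hp.max_iter + 1

    def test_label_symmetry_under_equal_weights(self, rng, small_hp):
        lengths, f = (6, 4), 5
        mats = [rng.uniform(0, 2, (f, t)) for t in lengths]
        w = WeightScheme(lambda_r0=0.5, lambda_r1=0.5, lambda_w=0.1, alpha=0.0)
        _, t0 = fit(SegmentSet([m.copy() for m in mats], [0, 0]), None, small_hp, w)
        _, t1 = fit(SegmentSet([m.copy() for m in mats], [1, 1]), None, small_hp, w)
        np.testing.assert_array_equal(t0, t1)

    def test_sweep_descent(self, rng):
        """Each update sweep decreases the objective (evaluated at the sweep's
        normalization state) — the descent property of the multiplicative
        rules.  The recorded trace, taken after the per-sweep renormalization,
        may transiently rise because renormalization re-expresses the
        Frobenius penalties; that is exercised separately in acceptance."""
        segs = random_segments(rng, f=8, lengths=(10, 8), labels=(0, 1))
        y = rng.uniform(0, 2, (8, 12))
        hp = HyperParams(k_r=3, k_w=2, max_iter=1, seed=3)
        w = WeightScheme()
        model = init_model(segs, hp, with_training=True, t_y=12)
        for _ in range(25):
            before = objective(model, segs, y, w)
            update_shared_basis(model, segs, y, w)
            for l in range(len(segs)):
                update_wheeze_basis(model, segs, w, l)
            update_activations(model, segs, y)
            after = objective(model, segs, y, w)
            assert after <= before + 1e-8
            renormalize_model(model)

    def test_alpha_without_y_rejected(self, small_segments, small_hp):
        with pytest.raises(ValueError):
            fit(small_segments, None, small_hp, WeightScheme())

    def test_early_stop_truncates_trace(self, rng, small_hp):
        segs = random_segments(rng, f=4, lengths=(5,), labels=(0,))
        hp = HyperParams(k_r=2, k_w=2, max_iter=200, seed=1)
        _, trace = fit(segs, None, hp, WeightScheme(alpha=0.0), early_stop_tol=1e-3)
        assert len(trace) < 201
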