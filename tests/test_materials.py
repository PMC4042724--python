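"""Kinematics, SEF catalog, response functions and effective-stress splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fungqlv.materials as mat
from fungqlv import (MaterialModel, Stretches, elastic_cauchy, incompressible_lateral,
                     invariants_from_stretches, natural_state_residual, pk2_split,
                     pk2_split_principal, response_functions, sef_partials)
from fungqlv.materials import LockingError

stretch_triples = st.tuples(*(st.floats(0.5, 2.0) for _ in range(3)))


@pytest.mark.parametrize("lams, expected", [
    ((1, 1, 1), (3, 3, 1)),
    ((2, 2 ** -0.5, 2 ** -0.5), (5, 4.25, 1)),
    ((2, 3, 4), (29, 244, 576)),
])
def test_invariants_from_stretches(lams, expected):
    inv = invariants_from_stretches(Stretches(*lams))
    assert np.allclose((inv.I1, inv.I2, inv.I3), expected, rtol=1e-14)
    assert inv.I3 == pytest.approx(Stretches(*lams).J ** 2, rel=1e-14)


@pytest.mark.parametrize("lam, expected", [(1.0, 1.0), (4.0, 0.5), (1.5, 1.5 ** -0.5)])
def test_incompressible_lateral(lam, expected):
    assert incompressible_lateral(lam) == pytest.approx(expected, rel=1e-15)


def test_domain_errors():
    with pytest.raises(ValueError):
        Stretches(-1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        incompressible_lateral(0.0)
    with pytest.raises(ValueError):
        MaterialModel("mooney-rivlin", gamma=0.7)
    with pytest.raises(ValueError):
        MaterialModel("gent", kappa=1.0, Jm=-2.0)
    with pytest.raises(ValueError):
        MaterialModel("horgan-murphy", gamma=0.1)  # missing kappa
    with pytest.raises(ValueError):
        MaterialModel("no-such-model")


class TestSefPartials:
    def test_yeoh_identity_state(self):
        m = MaterialModel("yeoh2", mu=2.0, alpha=1.7)
        _, W1, W2, _ = sef_partials(m, (3.0, 3.0, 1.0))
        assert W1 == pytest.approx(m.mu / 2.0, rel=1e-15)
        assert W2 == 0.0

    def test_mooney_rivlin_partials_constant(self):
        m = MaterialModel("mooney-rivlin", mu=1.0, gamma=0.2)
        _, W1, W2, _ = sef_partials(m, (4.1, 5.3, 1.0))
        assert W1 == pytest.approx(0.5 * (0.5 + 0.2), rel=1e-15)
        assert W2 == pytest.approx(0.5 * (0.5 - 0.2), rel=1e-15)

    def test_gent_locking_limit(self):
        m = MaterialModel("gent", kappa=3.0, Jm=2.0)
        with pytest.raises(LockingError):
            sef_partials(m, (5.5, 6.0, 1.0))  # I1 - 3 = 2.5 >= Jm
        with pytest.raises(ValueError):
            sef_partials(m, (3.0, 3.0, -1.0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.tuples(*(st.floats(0.7, 1.5) for _ in range(3))))
    def test_partials_match_finite_differences(self, lams):
        """W1, W2, W3 are the invariant gradients of W (central differences).

        Stretches stay moderate so the Gent volumetric well (quartic in I3)
        does not drown the differences in cancellation noise.
        """
        inv = invariants_from_stretches(Stretches(*lams))
        for m in (MaterialModel("yeoh2", alpha=0.8),
                  MaterialModel("mooney-rivlin", gamma=-0.1),
                  MaterialModel("horgan-murphy", gamma=0.3, kappa=5.0),
                  MaterialModel("gent", kappa=5.0, Jm=50.0)):
            vals = np.array([inv.I1, inv.I2, inv.I3])
            _, *grads = sef_partials(m, tuple(vals))
            for k in range(3):
                d = 1e-6 * max(1.0, vals[k])
                up, dn = vals.copy(), vals.copy()
                up[k] += d
                dn[k] -= d
                fd = (sef_partials(m, tuple(up))[0] - sef_partials(m, tuple(dn))[0]) / (2 * d)
                scale = max(abs(fd), m.mu)
                assert abs(grads[k] - fd) < 1e-6 * scale


def test_sef_partials_against_sympy():
    """Symbolic differentiation of the catalog SEFs reproduces the partials."""
    sympy = pytest.importorskip("sympy")
    I1, I2, I3 = sympy.symbols("I1 I2 I3", positive=True)
    mu, kappa, gamma, Jm, alpha = 1.3, 4.0, 0.15, 30.0, 0.6
    exprs = {
        MaterialModel("yeoh2", mu=mu, alpha=alpha):
            mu / 4 * (2 * (I1 - 3) + alpha * (I1 - 3) ** 2),
        MaterialModel("mooney-rivlin", mu=mu, gamma=gamma):
            mu / 2 * ((sympy.Rational(1, 2) + gamma) * (I1 - 3)
                      + (sympy.Rational(1, 2) - gamma) * (I2 - 3)),
        MaterialModel("horgan-murphy", mu=mu, gamma=gamma, kappa=kappa):
            mu / 2 * ((sympy.Rational(1, 2) + gamma) * (I1 - 3 * I3 ** sympy.Rational(1, 3))
                      + (sympy.Rational(1, 2) - gamma) * (I2 - 3 * I3 ** sympy.Rational(2, 3)))
            + kappa / 2 * (sympy.sqrt(I3) - 1) ** 2,
        MaterialModel("gent", mu=mu, kappa=kappa, Jm=Jm):
            -mu / 2 * Jm * sympy.log(1 - (I1 - 3 * I3 ** sympy.Rational(1, 3)) / Jm)
            + kappa / 32 * (I3 - 1 - sympy.log(I3)) ** 4,
    }
    point = {I1: 3.9, I2: 4.4, I3: 1.21}
    for m, W in exprs.items():
        got = sef_partials(m, (3.9, 4.4, 1.21))
        want = [W] + [sympy.diff(W, v) for v in (I1, I2, I3)]
        for g, w in zip(got, want):
            assert float(g) == pytest.approx(float(w.subs(point)), rel=1e-12, abs=1e-12)


class TestResponseFunctions:
    def test_sum_vanishes_at_identity(self, compressible_model):
        """T^e(I) = (b0 + b1 + b-1) I = 0 at the natural state."""
        b0, b1, bm1 = response_functions(compressible_model, (3.0, 3.0, 1.0))
        assert abs(b0 + b1 + bm1) < 1e-12 * compressible_model.mu

    def test_gamma_half_has_no_inverse_response(self):
        """With W2 = 0 (neo-Hookean shear response) beta_-1 vanishes."""
        m = MaterialModel("horgan-murphy", gamma=0.5, kappa=4.0)
        _, _, bm1 = response_functions(m, (4.0, 5.0, 1.0))
        assert bm1 == 0.0

    def test_mooney_rivlin_incompressible_limit(self):
        # beta1 = mu (1/2 + gamma), beta_-1 = -mu (1/2 - gamma) at I3 = 1
        m = MaterialModel("horgan-murphy", mu=2.0, gamma=0.2, kappa=9.0)
        _, b1, bm1 = response_functions(m, (4.0, 5.0, 1.0))
        assert b1 == pytest.approx(2.0 * 0.7, rel=1e-14)
        assert bm1 == pytest.approx(-2.0 * 0.3, rel=1e-14)

    def test_requires_compressible(self):
        with pytest.raises(ValueError):
            response_functions(MaterialModel("yeoh2"), (3.0, 3.0, 1.0))


class TestElasticCauchy:
    def test_zero_at_identity(self, any_model):
        T = elastic_cauchy(any_model, Stretches(1.0, 1.0, 1.0))
        assert np.max(np.abs(T)) < 1e-12 * any_model.mu

    def test_neo_hookean_uniaxial_difference(self):
        m = MaterialModel("yeoh2", mu=1.0, alpha=0.0)
        for lam in (0.8, 1.3, 1.9):
            T = elastic_cauchy(m, Stretches(lam, lam ** -0.5, lam ** -0.5))
            assert T[0] - T[1] == pytest.approx(lam ** 2 - 1 / lam, rel=1e-13)

    def test_trace_matches_component_sum(self, compressible_model):
        s = Stretches(1.4, 0.8, 1.1)
        T = elastic_cauchy(compressible_model, s)
        b0, b1, bm1 = response_functions(compressible_model, invariants_from_stretches(s))
        B = s.as_array() ** 2
        assert np.trace(np.diag(T)) == pytest.approx(
            3 * b0 + b1 * B.sum() + bm1 * (1 / B).sum(), rel=1e-13)


class TestPk2Split:
    def test_vanishes_at_identity(self, compressible_model):
        split = pk2_split(compressible_model, Stretches(1.0, 1.0, 1.0))
        assert np.max(np.abs(split.pi_d)) < 1e-12 * compressible_model.mu
        assert np.max(np.abs(split.pi_h)) < 1e-12 * compressible_model.mu

    def test_incompressible_uniaxial_closed_forms(self):
        """Axial/lateral deviatoric components match the worked uniaxial forms."""
        m = MaterialModel("mooney-rivlin", mu=1.0, gamma=0.1)
        lam = 1.6
        split = pk2_split(m, Stretches(lam, lam ** -0.5, lam ** -0.5))
        inv = invariants_from_stretches(Stretches(lam, lam ** -0.5, lam ** -0.5))
        _, W1, W2, _ = sef_partials(m, inv)
        assert split.pi_d[0] == pytest.approx(
            2 * (2 / 3) * (W1 + W2 / lam) * (1 - lam ** -3), rel=1e-12)
        assert split.pi_d[1] == pytest.approx(
            2 * (1 / 3) * (W1 + W2 / lam) * (1 - lam ** 3), rel=1e-12)
        assert split.pi_h is None

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(stretch_triples)
    def test_pushforward_structure(self, lams):
        """J^-1 F Pi_D F^T is trace-free; J^-1 F Pi_H F^T is isotropic."""
        s = Stretches(*lams)
        for m in (MaterialModel("horgan-murphy", gamma=-0.25, kappa=6.0),
                  MaterialModel("gent", kappa=6.0, Jm=60.0)):
            split = pk2_split(m, s)
            push_d = s.as_array() ** 2 * split.pi_d / s.J
            push_h = s.as_array() ** 2 * split.pi_h / s.J
            assert abs(np.sum(push_d)) < 1e-10 * m.mu
            assert np.max(np.abs(push_h - push_h[0])) < 1e-10 * m.mu

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(stretch_triples)
    def test_invariant_and_principal_forms_agree(self, lams):
        s = Stretches(*lams)
        for m in (MaterialModel("horgan-murphy", gamma=0.4, kappa=3.0),
                  MaterialModel("gent", kappa=3.0, Jm=60.0)):
            a = pk2_split(m, s)
            b = pk2_split_principal(m, s)
            assert np.max(np.abs(a.pi_d - b.pi_d)) < 1e-10 * m.mu
            assert np.max(np.abs(a.pi_h - b.pi_h)) < 1e-10 * m.mu


def test_mooney_rivlin_gamma_half_is_neo_hookean():
    mr = MaterialModel("mooney-rivlin", mu=1.4, gamma=0.5)
    nh = MaterialModel("yeoh2", mu=1.4, alpha=0.0)
    for inv in [(3.0, 3.0, 1.0), (4.7, 5.9, 1.0), (3.2, 3.4, 1.0)]:
        assert sef_partials(mr, inv)[:3] == pytest.approx(sef_partials(nh, inv)[:3])


class TestNaturalState:
    def test_catalog_residuals_vanish(self):
        for m in (MaterialModel("horgan-murphy", mu=1.7, gamma=-0.31, kappa=11.0),
                  MaterialModel("horgan-murphy", mu=0.9, gamma=0.5, kappa=0.4),
                  MaterialModel("gent", mu=2.2, kappa=7.0, Jm=3.3),
                  MaterialModel("gent", mu=0.5, kappa=100.0, Jm=80.0)):
            assert abs(natural_state_residual(m)) <= 1e-12 * m.mu

    def test_corrupted_w3_offset_is_reported(self, monkeypatch):
        """Shifting W3 by a constant c shifts the residual by exactly c."""
        m = MaterialModel("horgan-murphy", gamma=0.2, kappa=8.0)
        original = mat.sef_partials
        c = 0.37

        def corrupted(model, inv):
            W, W1, W2, W3 = original(model, inv)
            return W, W1, W2, W3 + c

        monkeypatch.setattr(mat, "sef_partials", corrupted)
        assert mat.natural_state_residual(m) == pytest.approx(c, rel=1e-12)

    def test_incompressible_models_rejected(self):
        with pytest.raises(ValueError):
            natural_state_residual(MaterialModel("yeoh2"))
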