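"""Constitutive-model tests: Ogden, Prony, flesh, ribs, principal stresses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from palpsim import materials as mat
from palpsim.materials import (
    OgdenParams,
    PronySeries,
    RibState,
    ViscoState,
    default_cards,
    flesh_stress,
    ogden_cauchy_stress,
    ogden_energy,
    principal_stresses,
    prony_modulus,
    rib_plastic_update,
    visco_overstress_update,
)

RNG = np.random.default_rng(42)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# Material cards
# ---------------------------------------------------------------------------


def test_default_cards_match_published_tables(cards):
    assert cards.flesh.density == 1.06e-6
    assert cards.flesh.bulk_modulus == 2.0
    assert cards.flesh.damping_coefficient == 0.4
    assert cards.flesh.shear_modulus == 400e-5
    assert cards.rib.young_modulus == 0.04
    assert cards.rib.poisson_ratio == 0.45
    assert cards.rib.yield_stress == 0.0018
    assert cards.rib.tangent_modulus == 0.001
    assert cards.liver_ogden.poisson_ratio == 0.49
    assert cards.liver_ogden.density == 1.05e-6
    mus = cards.liver_ogden.mus
    alphas = cards.liver_ogden.alphas
    assert np.allclose(mus, [8.914e-8, 9.965e-9, -9.275e-8])
    assert np.allclose(alphas, [1.0, 19.0656, -10.9604])
    # net ground-state stiffness positive despite the negative pair
    assert cards.liver_ogden.ground_shear_modulus > 0


def test_cards_json_roundtrip(cards, tmp_path):
    path = tmp_path / "cards.json"
    cards.to_json(path)
    back = mat.MaterialCards.from_json(path)
    assert back == cards


def test_invalid_cards_rejected():
    with pytest.raises(ValueError):
        OgdenParams(terms=((1e-6, -2.0),), poisson_ratio=0.49, density=1e-6)  # negative stiffness
    with pytest.raises(ValueError):
        PronySeries(terms=((1e-6, -1.0),))
    with pytest.raises(ValueError):
        mat.RibCard(density=1e-6, young_modulus=0.04, poisson_ratio=0.45,
                    yield_stress=0.0018, tangent_modulus=0.05)  # Et > E


# ---------------------------------------------------------------------------
# Ogden energy and stress
# ---------------------------------------------------------------------------


def test_ogden_energy_reference_state_and_symmetry(cards):
    p = cards.liver_ogden
    assert ogden_energy((1.0, 1.0, 1.0), p) == pytest.approx(0.0, abs=1e-18)
    lam = (1.3, 0.9, 1.05)
    vals = {ogden_energy(perm, p) for perm in [(lam[i], lam[j], lam[k])
            for i, j, k in [(0, 1, 2), (1, 0, 2), (2, 1, 0), (1, 2, 0)]]}
    assert max(vals) - min(vals) < 1e-18


def test_ogden_energy_matches_term_by_term_sum(cards):
    # independent hand evaluation of the three-term sum at an isochoric state
    l1 = 1.2
    lt = 1.0 / np.sqrt(1.2)
    expected = 0.0
    for mu, alpha in [(8.914e-8, 1.0), (9.965e-9, 19.0656), (-9.275e-8, -10.9604)]:
        expected += (mu / alpha) * (l1**alpha + 2.0 * lt**alpha - 3.0)
    got = ogden_energy((l1, lt, lt), cards.liver_ogden)
    assert got == pytest.approx(expected, rel=1e-14)


def test_ogden_energy_rejects_nonpositive_stretch(cards):
    with pytest.raises(ValueError):
        ogden_energy((1.0, -0.5, 1.0), cards.liver_ogden)


def test_ogden_stress_zero_at_identity(cards):
    sig = ogden_cauchy_stress(np.eye(3), cards.liver_ogden)
    assert np.allclose(sig, 0.0, atol=1e-18)


def test_ogden_stress_objectivity(cards):
    rng = np.random.default_rng(3)
    f = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    assert np.linalg.det(f) > 0
    r = random_rotation(rng)
    s1 = ogden_cauchy_stress(r @ f, cards.liver_ogden)
    s2 = r @ ogden_cauchy_stress(f, cards.liver_ogden) @ r.T
    assert np.allclose(s1, s2, atol=1e-18 + 1e-10 * np.abs(s2).max())


def test_ogden_uniaxial_matches_energy_derivative(cards):
    # isochoric uniaxial: axial Cauchy stress from central-difference of the
    # energy, sigma_axial - sigma_lateral = lambda * dPsi/dlambda (J = 1)
    p = cards.liver_ogden
    lam = 1.1
    lt = 1.0 / np.sqrt(lam)
    f = np.diag([lam, lt, lt])
    sig = ogden_cauchy_stress(f, p)
    h = 1e-6

    def psi(la):
        return ogden_energy((la, 1.0 / np.sqrt(la), 1.0 / np.sqrt(la)), p)

    dpsi = (psi(lam + h) - psi(lam - h)) / (2.0 * h)
    assert sig[0, 0] - sig[1, 1] == pytest.approx(lam * dpsi, rel=1e-5)


def test_ogden_two_route_second_piola_kirchhoff(cards):
    """Cauchy route equals (1/J) F S F^T with S built from the C-eigendecomposition."""
    p = cards.liver_ogden
    rng = np.random.default_rng(7)
    for _ in range(20):
        f = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        j = np.linalg.det(f)
        c = f.T @ f
        w, n = np.linalg.eigh(c)
        lam = np.sqrt(w)
        lbar = lam * j ** (-1.0 / 3.0)
        # principal Cauchy stresses, term by term
        sig_p = np.zeros(3)
        for muk, alk in p.terms:
            la = lbar**alk
            sig_p += muk * (la - la.mean()) / j
        sig_p += p.bulk_modulus * (j - 1.0)
        s2 = (n * (j * sig_p / lam**2)[None, :]) @ n.T  # 2nd Piola–Kirchhoff
        sig_ref = f @ s2 @ f.T / j
        sig = ogden_cauchy_stress(f, p)
        assert np.allclose(sig, sig_ref, rtol=1e-8, atol=1e-20)


def test_ogden_energy_is_stress_potential_along_isochoric_path(cards):
    """Path integral of sigma:D over an isochoric stretch path recovers the energy."""
    p = cards.liver_ogden
    n = 4000
    lams = np.linspace(1.0, 1.25, n + 1)
    work = 0.0
    for k in range(n):
        lam_mid = 0.5 * (lams[k] + lams[k + 1])
        dlam = lams[k + 1] - lams[k]
        lt = 1.0 / np.sqrt(lam_mid)
        f = np.diag([lam_mid, lt, lt])
        sig = ogden_cauchy_stress(f, p)
        # D = diag(ldot/l, -ldot/2l, -ldot/2l); sigma:D dt, J=1
        dt_rate = np.array([1.0, -0.5, -0.5]) * (dlam / lam_mid)
        work += float(np.sum(np.diag(sig) * dt_rate))
    psi = ogden_energy((lams[-1], 1 / np.sqrt(lams[-1]), 1 / np.sqrt(lams[-1])), p)
    assert work == pytest.approx(psi, rel=1e-4)


def test_ogden_inversion_rejected(cards):
    with pytest.raises(mat.InversionError):
        ogden_cauchy_stress(np.diag([1.0, 1.0, -1.0]), cards.liver_ogden)


# ---------------------------------------------------------------------------
# Prony series and visco overstress
# ---------------------------------------------------------------------------


def test_prony_instantaneous_modulus_is_printed_sum(cards):
    # hand sum of the three printed shear moduli
    assert prony_modulus(0.0, cards.liver_prony) == pytest.approx(1.005881e-4, rel=1e-12)


def test_prony_monotone_decay_to_zero(cards):
    ts = np.linspace(0.0, 5e4, 200)
    g = prony_modulus(ts, cards.liver_prony)
    assert np.all(np.diff(g) < 0)
    assert g[-1] < 1e-9


def test_prony_single_term_closed_form():
    series = PronySeries(terms=((2.5e-5, 40.0),))
    assert prony_modulus(40.0, series) == pytest.approx(2.5e-5 * np.exp(-1.0), rel=1e-14)
    with pytest.raises(ValueError):
        prony_modulus(-1.0, series)


def test_visco_free_decay_is_exact_exponential(cards):
    series = cards.liver_prony
    state = ViscoState.zero(series)
    de = np.diag([0.01, -0.005, -0.005])
    dt = 0.5
    state, _ = visco_overstress_update(state, de, dt, series)
    h0 = state.h.copy()
    for k in range(1, 6):
        state, _ = visco_overstress_update(state, np.zeros((3, 3)), dt, series)
        expected = h0 * np.exp(-k * dt / series.taus)[:, None, None]
        assert np.allclose(state.h, expected, rtol=1e-12)


def test_visco_internal_tensors_deviatoric(cards):
    state = ViscoState.zero(cards.liver_prony)
    rng = np.random.default_rng(0)
    for _ in range(10):
        de = 0.01 * rng.standard_normal((3, 3))
        state, s = visco_overstress_update(state, de, 0.3, cards.liver_prony)
    assert abs(np.trace(s)) < 1e-10 * max(np.abs(s).max(), 1e-30)
    for h in state.h:
        assert abs(np.trace(h)) < 1e-10


def _trapezoid_convolution(times, strains, series):
    """Direct quadrature of the relaxation convolution S(t) = int G(t-T) dE/dT dT."""
    out = np.zeros((len(times), 3, 3))
    rates = np.gradient(strains, times, axis=0)
    for i, t in enumerate(times):
        g = prony_modulus(t - times[: i + 1], series)
        integrand = g[:, None, None] * rates[: i + 1]
        out[i] = np.trapezoid(integrand, times[: i + 1], axis=0)
    return out


def test_visco_recurrence_matches_trapezoid_convolution(cards):
    """Step-and-hold strain: recurrence vs direct Eq-convolution within 1%."""
    series = cards.liver_prony
    dt = 0.05
    times = np.arange(0.0, 25.0 + dt / 2, dt)
    de_step = mat._dev(np.diag([0.02, -0.01, -0.01]))
    ramp_end = 1.0  # strain applied over the first 1 ms, then held
    strains = np.minimum(times / ramp_end, 1.0)[:, None, None] * de_step
    ref = _trapezoid_convolution(times, strains, series)

    state = ViscoState.zero(series)
    got = np.zeros_like(ref)
    for i in range(1, len(times)):
        de = strains[i] - strains[i - 1]
        state, s = visco_overstress_update(state, de, dt, series)
        got[i] = s
    scale = np.abs(ref[-1]).max()
    late = times > ramp_end  # compare after the ramp (quadrature needs smoothness)
    assert np.max(np.abs(got[late] - ref[late])) < 0.01 * scale


def test_visco_exact_for_constant_rate_ramp(cards):
    """Any step subdivision of a constant-rate ramp hits the continuous
    convolution: the per-term update integrates a constant strain rate
    exactly, so refinement in dt changes nothing but roundoff."""
    series = cards.liver_prony
    de_total = mat._dev(np.diag([0.03, -0.01, -0.02]))
    t_end = 10.0
    # continuous convolution of a constant rate: sum_i G_i tau_i rate (1 - e^(-t/tau_i))
    rate = de_total / t_end
    exact = sum(
        gi * ti * (1.0 - np.exp(-t_end / ti)) for gi, ti in series.terms
    ) * rate

    def run(nsteps):
        dt = t_end / nsteps
        state = ViscoState.zero(series)
        for _ in range(nsteps):
            state, s = visco_overstress_update(state, de_total / nsteps, dt, series)
        return s

    scale = np.abs(exact).max()
    for nsteps in (50, 100, 400):
        assert np.abs(run(nsteps) - exact).max() < 1e-12 * scale


def test_visco_linear_in_strain_history(cards):
    """Superposition: response to (A + B) equals response to A plus response to B."""
    series = cards.liver_prony
    rng = np.random.default_rng(5)
    hist_a = 0.01 * rng.standard_normal((8, 3, 3))
    hist_b = 0.01 * rng.standard_normal((8, 3, 3))
    dt = 0.4

    def responses(hist):
        state = ViscoState.zero(series)
        out = []
        for de in hist:
            state, s = visco_overstress_update(state, de, dt, series)
            out.append(s)
        return np.array(out)

    ra, rb, rab = responses(hist_a), responses(hist_b), responses(hist_a + hist_b)
    assert np.allclose(rab, ra + rb, rtol=1e-12, atol=1e-25)


# ---------------------------------------------------------------------------
# Flesh
# ---------------------------------------------------------------------------


def test_flesh_zero_at_rest(cards):
    sig = flesh_stress(np.eye(3), np.zeros((3, 3)), cards.flesh)
    assert np.allclose(sig, 0.0, atol=1e-18)


def test_flesh_pure_volumetric_response(cards):
    j = 0.95
    f = j ** (1.0 / 3.0) * np.eye(3)
    sig = flesh_stress(f, np.zeros((3, 3)), cards.flesh)
    pressure = -np.trace(sig) / 3.0
    assert pressure == pytest.approx(-cards.flesh.bulk_modulus * (j - 1.0), rel=1e-12)
    dev = sig - np.trace(sig) / 3.0 * np.eye(3)
    assert np.abs(dev).max() < 1e-15


def test_flesh_simple_shear_closed_form(cards):
    gamma = 0.1
    f = np.eye(3)
    f[0, 1] = gamma
    sig = flesh_stress(f, np.zeros((3, 3)), cards.flesh)
    # isochoric neo-Hookean simple shear: sigma_12 = G * gamma exactly
    assert sig[0, 1] == pytest.approx(cards.flesh.shear_modulus * gamma, rel=1e-12)


# ---------------------------------------------------------------------------
# Ribs
# ---------------------------------------------------------------------------


def test_rib_hardening_modulus_value(cards):
    # H = E Et / (E - Et) from the printed constants
    assert cards.rib.hardening_modulus == pytest.approx(1.0256e-3, rel=1e-3)


def _uniaxial_stress_step(state, card, d_axial):
    """Apply an axial strain increment while iterating the lateral strain so
    the lateral stress stays (approximately) zero: uniaxial-stress driver."""
    from scipy.optimize import brentq
    import copy

    def lateral_stress(d_lat):
        trial = copy.deepcopy(state)
        deps = np.diag([d_axial, d_lat, d_lat])
        sig, _ = rib_plastic_update(deps, trial, card)
        return sig[1, 1]

    d_lat = brentq(lateral_stress, -2 * abs(d_axial) - 1e-12, 2 * abs(d_axial) + 1e-12, xtol=1e-14)
    sig, new_state = rib_plastic_update(np.diag([d_axial, d_lat, d_lat]), state, card)
    return sig, new_state


def test_rib_elastic_slope_below_yield(cards):
    state = RibState.zero()
    eps = 0.0
    d = 5e-4
    for _ in range(20):
        sig, state = _uniaxial_stress_step(state, cards.rib, d)
        eps += d
    assert sig[0, 0] < cards.rib.yield_stress  # still elastic
    assert sig[0, 0] / eps == pytest.approx(cards.rib.young_modulus, rel=1e-6)


def test_rib_post_yield_slope_approaches_tangent_modulus(cards):
    state = RibState.zero()
    eps = 0.0
    d = 2e-3
    history = []
    for _ in range(120):
        sig, state = _uniaxial_stress_step(state, cards.rib, d)
        eps += d
        history.append((eps, sig[0, 0]))
    (e0, s0), (e1, s1) = history[-20], history[-1]
    slope = (s1 - s0) / (e1 - e0)
    assert slope == pytest.approx(cards.rib.tangent_modulus, rel=0.02)
    assert state.eq_plastic_strain > 0


# ---------------------------------------------------------------------------
# Principal stresses
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "tensor, expected",
    [
        (np.eye(3), (1.0, 1.0, 1.0)),
        (np.diag([3.0, 1.0, 2.0]), (1.0, 2.0, 3.0)),
        (np.array([[0, 1, 0], [1, 0, 0], [0, 0, 2.0]]), (-1.0, 1.0, 2.0)),
    ],
)
def test_principal_stresses_known_cases(tensor, expected):
    ps = principal_stresses(tensor)
    assert ps.as_array() == pytest.approx(np.array(expected), abs=1e-12)
    assert ps.sigma1 <= ps.sigma2 <= ps.sigma3


def test_principal_stresses_rejects_asymmetric():
    bad = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
    with pytest.raises(ValueError):
        principal_stresses(bad)


@settings(deadline=None, max_examples=50)
@given(st.integers(0, 2**31 - 1))
def test_principal_stresses_preserve_invariants(seed):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((3, 3))
    s = 0.5 * (a + a.T)
    ps = principal_stresses(s).as_array()
    assert np.sum(ps) == pytest.approx(np.trace(s), rel=1e-10, abs=1e-10)
    assert np.prod(ps) == pytest.approx(np.linalg.det(s), rel=1e-8, abs=1e-10)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_stress_operators_return_symmetric_tensors(cards, seed):
    rng = np.random.default_rng(seed)
    f = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    if np.linalg.det(f) <= 0.05:
        return
    d = rng.standard_normal((3, 3))
    for sig in (
        ogden_cauchy_stress(f, cards.liver_ogden),
        flesh_stress(f, d, cards.flesh),
        rib_plastic_update(0.001 * (d + d.T), RibState.zero(), cards.rib)[0],
    ):
        assert np.array_equal(sig, sig.T)
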