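import numpy as np
import pytest

from mycflux.polii import (
    ClusterProfile,
    PolymeraseRates,
    elongation_from_synthesis,
    explained_variance,
    fix_parameter_in_silico,
    infer_rates,
    simulate_compartments,
    single_parameter_variance,
    stage1_finite_difference,
)

KNOTS = np.array([0.0, 1 / 6, 0.5, 1.0, 2.0, 4.0])
INIT = (30.0, 20.0, 10.0)  # steady state of p1=60, p2=2, p3=3, p4=6


def const_rates(p1=60.0, p2=2.0, p3=3.0, p4=6.0, mode="linear", knots=KNOTS):
    n = knots.size if mode == "linear" else knots.size - 1
    return PolymeraseRates(knots, p1=np.full(n, p1), p2=np.full(n, p2),
                           p3=np.full(n, p3), p4=np.full(n, p4), mode=mode)


def test_steady_state_flux_conservation():
    Pr, Gb, Te, k1 = simulate_compartments(const_rates(), INIT, KNOTS)
    assert np.allclose(Pr, 30.0, atol=1e-8)
    assert np.allclose(Gb, 20.0, atol=1e-8)
    assert np.allclose(Te, 10.0, atol=1e-8)
    # k1 = p1 = p2*Pr = p3*Gb = p4*Te at steady state
    assert np.allclose(k1, 60.0, atol=1e-7)


def test_promoter_shutoff_decays_exponentially():
    rates = const_rates(p1=0.0)
    times = np.linspace(0, 2, 21)
    Pr, _, _, _ = simulate_compartments(rates, INIT, times)
    assert np.allclose(Pr, 30.0 * np.exp(-2.0 * times), rtol=1e-6, atol=1e-8)


def test_mass_balance_of_compartment_chain():
    knots = KNOTS
    rates = PolymeraseRates(knots, p1=np.array([60, 90, 70, 40, 50, 55.0]),
                            p2=2.0, p3=3.0, p4=6.0)
    ts = np.linspace(0, 4, 800)
    Pr, Gb, Te, _ = simulate_compartments(rates, INIT, ts)
    total = Pr + Gb + Te
    dtot = np.gradient(total, ts)
    expected = rates("p1", ts) - rates("p4", ts) * Te
    # mask the ends and the rate kinks, where the central difference of a
    # piecewise-linear forcing is not second-order
    near_knot = np.min(np.abs(ts[:, None] - KNOTS[None, :]), axis=1) < 0.02
    ok = ~near_knot
    ok[:2] = ok[-2:] = False
    assert np.max(np.abs(dtot - expected)[ok]) < 0.02


def test_elongation_ratio():
    p3, flagged = elongation_from_synthesis([60.0, 120.0], [20.0, 40.0])
    assert np.allclose(p3, 3.0)
    assert not flagged.any()
    p3z, flz = elongation_from_synthesis([60.0], [0.0])
    assert np.isnan(p3z[0]) and flz[0]


def test_piecewise_constant_round_trip_with_negative_p1():
    knots = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 4.0])
    truth = PolymeraseRates(
        knots,
        p1=np.array([60.0, 90.0, -20.0, 40.0, 50.0]),
        p2=np.array([2.0, 3.0, 2.5, 2.2, 2.0]),
        p3=np.array([3.0, 2.0, 2.2, 2.8, 3.0]),
        p4=np.array([6.0, 5.0, 6.0, 5.5, 6.0]),
        mode="constant",
    )
    Pr, Gb, Te, k1 = simulate_compartments(truth, INIT, knots)
    est = infer_rates(ClusterProfile(1, knots, Pr, Gb, Te, k1), mode="constant")
    for name in ("p1", "p2", "p3", "p4"):
        t, e = getattr(truth, name), getattr(est, name)
        assert np.max(np.abs(e - t) / np.abs(t)) < 1e-6


def test_steady_state_only_input_gives_closed_form_rates():
    knots = KNOTS
    flat = ClusterProfile(1, knots, np.full(6, 30.0), np.full(6, 20.0),
                          np.full(6, 10.0), np.full(6, 60.0))
    est = infer_rates(flat, mode="constant")
    assert np.allclose(est.p1, 60.0, rtol=1e-6)
    assert np.allclose(est.p2, 2.0, rtol=1e-6)
    assert np.allclose(est.p3, 3.0, rtol=1e-6)
    assert np.allclose(est.p4, 6.0, rtol=1e-6)


def test_inference_equivariant_to_density_rescaling():
    knots = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
    truth = PolymeraseRates(knots, p1=np.array([60, 80, 50, 55.0]),
                            p2=np.array([2, 2.5, 2.2, 2.0]),
                            p3=np.array([3.0, 2.6, 3.2, 3.0]),
                            p4=np.array([6.0, 6.0, 5.0, 6.0]), mode="constant")
    Pr, Gb, Te, k1 = simulate_compartments(truth, INIT, knots)
    est = infer_rates(ClusterProfile(1, knots, Pr, Gb, Te, k1), mode="constant")
    c = 7.3  # rescale all densities and synthesis by the same factor
    est_c = infer_rates(ClusterProfile(1, knots, c * Pr, c * Gb, c * Te, c * k1),
                        mode="constant")
    assert np.allclose(est_c.p1, c * est.p1, rtol=1e-6)
    for name in ("p2", "p3", "p4"):
        assert np.allclose(getattr(est_c, name), getattr(est, name), rtol=1e-6)


def test_stage1_initialization_close_on_slow_dynamics():
    knots = np.round(np.arange(0, 1.0001, 0.05), 9)
    truth = PolymeraseRates(knots, p1=np.where(knots[:-1] < 0.5, 60.0, 80.0),
                            p2=np.full(20, 2.0), p3=np.full(20, 3.0),
                            p4=np.full(20, 6.0), mode="constant")
    Pr, Gb, Te, k1 = simulate_compartments(truth, INIT, knots)
    fd = stage1_finite_difference(ClusterProfile(1, knots, Pr, Gb, Te, k1))
    assert np.max(np.abs(fd.p2 - 2.0) / 2.0) < 0.01
    assert np.max(np.abs(fd.p4 - 6.0) / 6.0) < 0.01


def make_single_varying(which):
    vals = {
        "p1": [60, 80, 100, 90, 80, 80.0],
        "p2": [2, 2.6, 3.2, 3.0, 2.6, 2.4],
        "p3": [3, 2.2, 1.8, 2.0, 2.6, 3.0],
        "p4": [6, 4.5, 3.5, 4.0, 5.0, 6.0],
    }
    kw = dict(p1=60.0, p2=2.0, p3=3.0, p4=6.0)
    kw[which] = np.array(vals[which])
    truth = PolymeraseRates(KNOTS, mode="linear", **kw)
    Pr, Gb, Te, k1 = simulate_compartments(truth, INIT, KNOTS)
    return ClusterProfile(1, KNOTS, Pr, Gb, Te, k1)


@pytest.mark.parametrize("which", ["p1", "p2", "p3", "p4"])
def test_single_parameter_attribution(which):
    prof = make_single_varying(which)
    full = infer_rates(prof, mode="linear")
    evs = {w: single_parameter_variance(prof, w, rates_full=full)[0]
           for w in ("p1", "p2", "p3", "p4")}
    assert max(evs, key=evs.get) == which
    assert evs[which] >= 0.95
    # the full model is never worse than any single-parameter model
    assert explained_variance(prof, full) >= max(evs.values()) - 1e-9


def test_freezing_a_constant_parameter_is_harmless():
    prof = make_single_varying("p1")
    out = fix_parameter_in_silico(prof, "p4")
    assert abs(out["ev_drop"]) < 1e-6


def test_freezing_decreasing_p3_degrades_genebody_prediction():
    truth = PolymeraseRates(KNOTS, p1=60.0, p2=2.0,
                            p3=np.array([3, 2.2, 1.6, 1.5, 1.8, 2.4]), p4=6.0)
    Pr, Gb, Te, k1 = simulate_compartments(truth, INIT, KNOTS)
    prof = ClusterProfile(1, KNOTS, Pr, Gb, Te, k1)
    out = fix_parameter_in_silico(prof, "p3")
    assert out["ss_frozen"]["Gb"] > 2 * max(out["ss_full"]["Gb"], 1e-12)
    assert out["ss_frozen"]["k1"] > 2 * max(out["ss_full"]["k1"], 1e-12)


def test_freezing_all_parameters_fits_nothing():
    prof = make_single_varying("p2")
    full = infer_rates(prof, mode="linear")
    frozen = full
    for w in ("p1", "p2", "p3", "p4"):
        frozen = frozen.frozen(w)
    assert explained_variance(prof, frozen) <= 0.0


def test_flat_profile_variance_undefined():
    flat = ClusterProfile(1, KNOTS, np.full(6, 30.0), np.full(6, 20.0),
                          np.full(6, 10.0), np.full(6, 60.0))
    with pytest.raises(ValueError):
        explained_variance(flat, const_rates())


def test_positive_rate_validation():
    with pytest.raises(ValueError):
        PolymeraseRates(KNOTS, p1=60.0, p2=-1.0, p3=3.0, p4=6.0)
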