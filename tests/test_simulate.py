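import numpy as np
import pytest

from sulfidogen import community as com
from sulfidogen import kinetics as kin
from sulfidogen import simulate as sim


def test_same_seed_identical_output(treatments):
    p = sim.default_params("Gly")
    a = sim.simulate_microcosm(treatments["Gly"], p, 42)
    b = sim.simulate_microcosm(treatments["Gly"], p, 42)
    for name in a.observed:
        np.testing.assert_array_equal(a.observed[name], b.observed[name])
    c = sim.simulate_microcosm(treatments["Gly"], p, 43)
    assert not np.array_equal(a.observed["sulfide_uM"], c.observed["sulfide_uM"])


def test_controls_stay_flat(treatments, noiseless_params):
    for label in ("control", "uninoculated"):
        out = sim.simulate_microcosm(treatments[label], noiseless_params, 0)
        assert np.all(out.latent["sulfide_uM"] == 0.0)
        assert np.all(out.latent["OD600"] == 0.0)
        assert np.all(out.latent["pH"] == treatments[label].pH0)
    unin = sim.simulate_microcosm(treatments["uninoculated"], noiseless_params, 0)
    assert np.all(unin.latent["glycerol_mM"] == 5.0)


def test_stoichiometric_coupling_at_zero_noise(treatments, noiseless_params):
    out = sim.simulate_microcosm(treatments["Gly"], noiseless_params, 7)
    lat = out.latent
    consumed = lat["glycerol_consumed_mM"]
    # f_sulfate = 1: acetate 1.5 and sulfide 0.25 per glycerol, every step
    np.testing.assert_allclose(lat["acetate_mM"], 1.5 * consumed, atol=1e-9)
    np.testing.assert_allclose(lat["sulfide_produced_mM"], 0.25 * consumed, atol=1e-9)
    np.testing.assert_allclose(lat["sulfate_consumed_mM"], 0.25 * consumed, atol=1e-9)


def test_balances_every_step_at_zero_noise(treatments, noiseless_params):
    noiseless_params.f_sulfate = 0.8
    out = sim.simulate_microcosm(treatments["Gly+S"], noiseless_params, 11)
    lat = out.latent
    consumed = lat["glycerol_consumed_mM"]
    # carbon: 3 C per glycerol -> 2 C per acetate (incomplete oxidation only)
    np.testing.assert_allclose(3 * consumed, 2 * lat["acetate_mM"], atol=1e-9)
    # sulfur: produced sulfide = dissolved + precipitated (AVS pool)
    np.testing.assert_allclose(
        lat["sulfide_produced_mM"], lat["sulfide_uM"] / 1e3, atol=1e-9
    )
    # electrons: 2 e- per glycerol = 8 x sulfate + 2 x S0 consumed
    np.testing.assert_allclose(
        2 * consumed,
        8 * lat["sulfate_consumed_mM"] + 2 * lat["S0_consumed_mM"],
        atol=1e-9,
    )


def test_extent_at_exhaustion_matches_blended_yield(treatments):
    p = sim.SimParams(
        qmax_mM_d=0.4, f_sulfate=0.8, lag_mean_d=5.0, inoculum_spread=0.0, duration_d=40.0
    )
    p.noise_sigma = {k: 0.0 for k in p.noise_sigma}
    out = sim.simulate_microcosm(treatments["Gly+S"], p, 1)
    blended = 0.25 * 0.8 + 1.0 * 0.2
    assert out.latent["glycerol_mM"][-1] == pytest.approx(0.0, abs=1e-12)
    assert out.latent["sulfide_uM"][-1] == pytest.approx(5.0 * blended * 1e3, rel=1e-9)


def test_pH_non_decreasing_and_buffered(treatments, noiseless_params):
    out = sim.simulate_microcosm(treatments["Gly"], noiseless_params, 3)
    pH = out.latent["pH"]
    assert np.all(np.diff(pH) >= -1e-12)
    consumed_H = 0.5 * out.latent["glycerol_consumed_mM"][-1] * 1e-3
    assert pH[-1] - pH[0] == pytest.approx(
        consumed_H / noiseless_params.beta_mol_per_pH, rel=1e-9
    )


def test_metal_removal_sequence(treatments, noiseless_params):
    out = sim.simulate_microcosm(treatments["Gly"], noiseless_params, 5)
    lat = out.latent

    def depletion_time(key):
        vals = lat[key]
        idx = np.nonzero(vals <= 1e-9)[0]
        return out.times_d[idx[0]] if len(idx) else np.inf

    t_as, t_zn = depletion_time("As_mM"), depletion_time("Zn_mM")
    fe_final = lat["Fe_mM"][-1]
    assert t_as <= t_zn < np.inf
    assert 0 < fe_final < lat["Fe_mM"][0]  # Fe only partially removed


def test_rate_recovery_on_noiseless_output(treatments, noiseless_params):
    out = sim.simulate_microcosm(treatments["Gly"], noiseless_params, 9)
    est = kin.max_zero_order_rate(out.to_series().series("sulfide_uM"))
    assert est == pytest.approx(out.truth["zero_order_rate_uM_d"], rel=0.01)


def test_replicate_set_structure(treatments):
    p = sim.default_params("Gly")
    reps = sim.generate_replicate_set(treatments["Gly"], p, 3, seed=5)
    assert len({r.microcosm_id for r in reps}) == 3
    lags = [r.truth["lag_d"] for r in reps]
    assert len(set(lags)) > 1  # inoculum heterogeneity shifts lag
    # replicate k is stable when n changes
    reps2 = sim.generate_replicate_set(treatments["Gly"], p, 2, seed=5)
    np.testing.assert_array_equal(
        reps[0].observed["sulfide_uM"], reps2[0].observed["sulfide_uM"]
    )

    p.inoculum_spread = 0.0
    p.noise_sigma = {k: 0.0 for k in p.noise_sigma}
    same = sim.generate_replicate_set(treatments["Gly"], p, 2, seed=5)
    np.testing.assert_array_equal(
        same[0].observed["sulfide_uM"], same[1].observed["sulfide_uM"]
    )


def test_lag_ordering_between_treatments(treatments):
    # amended with both glycerol and S(0): earlier onset than glycerol alone
    lags = {"Gly": [], "Gly+S": []}
    for label in lags:
        for s in range(20):
            out = sim.simulate_microcosm(
                treatments[label],
                sim.default_params(label),
                np.random.default_rng([100 + s, len(label)]),
            )
            lag = kin.lag_time(out.to_series().series("sulfide_uM"))
            if lag is not None:
                lags[label].append(lag)
    assert np.mean(lags["Gly+S"]) < np.mean(lags["Gly"])


def test_s0_only_low_rate_no_acidification(treatments):
    p = sim.default_params("S0")
    p.noise_sigma = {k: 0.0 for k in p.noise_sigma}
    p.duration_d = 60.0
    out = sim.simulate_microcosm(treatments["S0"], p, 2)
    assert out.latent["sulfide_uM"][-1] <= p.s0_endogenous_extent_mM * 1e3 + 1e-9
    assert np.all(np.diff(out.latent["pH"]) >= -1e-12)


def test_community_table_converges_to_profile():
    profiles = {"g": {"a": 0.95, "b": 0.05}}
    table = sim.generate_community_table(
        profiles, n_samples=2, depth=1_000_000, concentration=1e7, seed=0
    )
    props = table.counts / table.counts.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(props[:, 0], 0.95, atol=5e-3)
    single = sim.generate_community_table(
        {"g": {"a": 1.0}}, n_samples=1, depth=1000, seed=0
    )
    assert com.shannon(single.counts[0]) == 0.0


def test_community_table_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        sim.generate_community_table({"g": {"a": 0.5}}, n_samples=1)


def test_tidy_output_round_trip(tmp_path, treatments):
    out = sim.simulate_microcosm(treatments["Gly"], sim.default_params("Gly"), 1)
    df = out.to_tidy()
    assert set(df.columns) == {
        "microcosm_id",
        "treatment",
        "generation",
        "analyte",
        "time_d",
        "value",
        "unit",
    }
    assert (df[df.analyte == "sulfide"].unit == "uM").all()
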