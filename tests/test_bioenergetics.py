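import math

import pytest

from sulfidogen import bioenergetics as bio
from sulfidogen import stoichiometry
from sulfidogen.bioenergetics import (
    ConditionSet,
    R_KJ,
    T_REF,
    delta_g_insitu,
    delta_g_standard,
    reaction_quotient,
    temperature_adjust,
)
from sulfidogen.chemistry import Reaction, Species


def test_null_reaction_has_zero_energy(thermo_table):
    gly = thermo_table["glycerol"].species
    rxn = Reaction(id="null", terms=[(gly, -1.0), (gly, 1.0)])
    assert delta_g_standard(rxn, thermo_table) == pytest.approx(0.0, abs=1e-12)


def test_missing_record_names_species(thermo_table, reactions):
    mystery = Species.from_formula("mystery", "C6H12O6")
    rxn = Reaction(
        id="x",
        terms=[(mystery, -1.0), (thermo_table["CO2"].species, 6.0)],
        reference_substrate=mystery,
    )
    with pytest.raises(KeyError, match="mystery"):
        delta_g_standard(rxn, thermo_table)


def test_quotient_is_one_at_unit_activities(reactions):
    cond = ConditionSet.standard()
    Q, lnQ = reaction_quotient(reactions["R1"], cond)
    assert Q == pytest.approx(1.0)
    assert lnQ == pytest.approx(0.0)


def test_quotient_R2_under_start_conditions(reactions, start_conditions):
    # hand product: (5e-6)^1.5 * (1e-6)^0.25 / (5e-3 * 0.14^0.25 * 10^-2.1)
    Q, lnQ = reaction_quotient(reactions["R2"], start_conditions)
    expected_ln = (
        1.5 * math.log(5e-6)
        + 0.25 * math.log(1e-6)
        - math.log(5e-3)
        - 0.25 * math.log(0.14)
        - 0.5 * math.log(10**-4.2)
    )
    assert lnQ == pytest.approx(expected_ln, abs=1e-9)
    assert Q == pytest.approx(1.46e-5, rel=5e-3)


def test_quotient_R5_under_start_conditions(reactions, start_conditions):
    # balanced disproportionation: 0.25 SO4^2- + 0.5 H+ + 0.75 H2S per S(0)
    _, lnQ = reaction_quotient(reactions["R5"], start_conditions)
    expected = (
        0.25 * math.log(0.14)
        + 0.5 * math.log(10**-4.2)
        + 0.75 * math.log(1e-6)
    )
    assert lnQ == pytest.approx(expected, abs=1e-9)


def test_temperature_adjust_identities():
    assert temperature_adjust(-214.0, None, T_REF, 291.0) == -214.0
    assert temperature_adjust(-214.0, -300.0, T_REF, T_REF) == pytest.approx(-214.0)
    # zero-entropy reaction: dH == dG stays put at any T
    assert temperature_adjust(-50.0, -50.0, T_REF, 350.0) == pytest.approx(-50.0)


def test_temperature_adjust_gibbs_helmholtz_value():
    # dG(298.15) = -214, dH = -300 -> dG(291) = -300 + (291/298.15)*86
    got = temperature_adjust(-214.0, -300.0, 298.15, 291.0)
    assert got == pytest.approx(-300.0 + (291.0 / 298.15) * 86.0, abs=1e-9)
    assert got == pytest.approx(-216.06, abs=0.01)


def test_insitu_equals_standard_at_Q1_and_Tref(reactions, thermo_table):
    cond = ConditionSet.standard()
    res = delta_g_insitu(reactions["R2"], thermo_table, cond, use_enthalpy=False)
    assert res.dG_insitu == pytest.approx(res.dG0_Tref, abs=1e-9)
    assert res.dG_insitu == pytest.approx(res.dG0_T + R_KJ * T_REF * res.lnQ, abs=1e-12)


def test_insitu_strictly_increasing_in_lnQ(reactions, thermo_table, start_conditions):
    base = delta_g_insitu(reactions["R2"], thermo_table, start_conditions)
    richer = ConditionSet(
        temperature=start_conditions.temperature,
        activities={**start_conditions.activities, "acetic_acid": 5e-4},
        gas_pressures=dict(start_conditions.gas_pressures),
        fixed_unit_activity=set(start_conditions.fixed_unit_activity),
        pH=start_conditions.pH,
    )
    more = delta_g_insitu(reactions["R2"], thermo_table, richer)
    assert more.lnQ > base.lnQ
    assert more.dG_insitu > base.dG_insitu


def test_per_substrate_energy_invariant_to_scaling(reactions, thermo_table):
    rxn = reactions["R1"]
    scaled = rxn.scaled(3.0)
    assert delta_g_standard(scaled, thermo_table) == pytest.approx(
        delta_g_standard(rxn, thermo_table), abs=1e-9
    )


def test_hess_additivity_recovers_complete_oxidation(thermo_table, half_reactions):
    # incomplete oxidation on S(0) plus full acetate oxidation on S(0)
    # (x1.5) must reproduce complete glycerol oxidation on S(0)
    r4 = stoichiometry.couple(half_reactions["glycerol_to_acetate"], half_reactions["S0_to_H2S"])
    acet = stoichiometry.couple(half_reactions["acetate_to_CO2"], half_reactions["S0_to_H2S"])
    r3 = stoichiometry.couple(half_reactions["glycerol_to_CO2"], half_reactions["S0_to_H2S"])
    total = delta_g_standard(r4, thermo_table) + 1.5 * delta_g_standard(acet, thermo_table)
    assert total == pytest.approx(delta_g_standard(r3, thermo_table), abs=1e-9)


def test_sign_pattern_of_reaction_set(reactions, thermo_table, start_conditions):
    for rid in ("R1", "R2", "R3", "R4"):
        res = delta_g_insitu(reactions[rid], thermo_table, start_conditions)
        assert res.dG0_Tref < 0
        assert res.dG_insitu < 0
    r5 = delta_g_insitu(reactions["R5"], thermo_table, start_conditions)
    assert r5.dG0_Tref > 0  # disproportionation unfavourable at standard state
    assert r5.dG_insitu < 0  # but slightly favourable at the incubation start


def test_condition_set_validation():
    with pytest.raises(ValueError):
        ConditionSet(temperature=-1.0)
    with pytest.raises(ValueError):
        ConditionSet(temperature=291.0, activities={"x": 0.0})
    cond = ConditionSet(temperature=291.0, pH=4.2)
    assert cond.activity("proton") == pytest.approx(10**-4.2)
    with pytest.raises(KeyError):
        cond.activity("unassigned_species")


def test_table2_analogue_dataframe(start_conditions):
    df = bio.table2_analogue(cond=start_conditions)
    assert list(df["reaction"]) == ["R1", "R2", "R3", "R4", "R5"]
    assert {"dG0_298K_kJ_per_mol", "dG_insitu_291K_kJ_per_mol"} <= set(df.columns)
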