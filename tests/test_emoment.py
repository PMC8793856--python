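"""eMOMENT MILP construction/solution, kinetics, rescaling, sampling, panels."""

from __future__ import annotations

import cobra
import numpy as np
import pandas as pd
import pytest

from ecgem.constraint_analysis import fba
from ecgem.emoment import (
    ConditionSpec,
    EnzymeConstraintSet,
    TransporterKinetics,
    abundance_variability,
    build_emoment,
    plasticity_cv,
    protein_pool_split,
    rescale_biomass,
    sample_abundances,
    simulate_condition_panel,
    solve_emoment,
    uptake_bound,
)


# ---------------------------------------------------------------------------
# Michaelis-Menten uptake bounds
# ---------------------------------------------------------------------------


def test_uptake_bound_half_saturation():
    k = TransporterKinetics(vmax=8.0, km=3.0)
    assert uptake_bound(k, 3.0) == pytest.approx(4.0)


def test_uptake_bound_cases():
    k = TransporterKinetics(vmax=10.0, km=5.0)
    assert uptake_bound(k, 0.0) == 0.0
    assert uptake_bound(k, 10.0) == pytest.approx(20.0 / 3.0)
    with pytest.raises(ValueError):
        uptake_bound(k, -1.0)
    with pytest.raises(ValueError):
        TransporterKinetics(vmax=0.0, km=1.0)


# ---------------------------------------------------------------------------
# Biomass rescaling
# ---------------------------------------------------------------------------


def _biomass_only_model(fractions: dict[str, float]) -> cobra.Model:
    model = cobra.Model("bm")
    weights = {"protein_c": 1.0, "lipid_c": 1.0, "carb_c": 1.0}
    for mid in weights:
        model.add_metabolites([cobra.Metabolite(mid, compartment="c")])
    bio = cobra.Reaction("BIOMASS", lower_bound=0, upper_bound=1000)
    model.add_reactions([bio])
    bio.add_metabolites({model.metabolites.get_by_id(m): -f for m, f in fractions.items()})
    model.objective = "BIOMASS"
    return model


def test_rescale_biomass_proportional_example():
    """protein .4 / lipid .3 / carb .3 at C=0.2 -> lipid .4, carb .4."""
    model = _biomass_only_model({"protein_c": 0.4, "lipid_c": 0.3, "carb_c": 0.3})
    weights = {"protein_c": 1.0, "lipid_c": 1.0, "carb_c": 1.0}
    out = rescale_biomass(model, 0.2, weights, {"protein_c"})
    coeffs = {m.id: -c for m, c in out.reactions.BIOMASS.metabolites.items()}
    assert coeffs["protein_c"] == pytest.approx(0.2)
    assert coeffs["lipid_c"] == pytest.approx(0.4)
    assert coeffs["carb_c"] == pytest.approx(0.4)


def test_rescale_biomass_identity_when_c_matches():
    model = _biomass_only_model({"protein_c": 0.4, "lipid_c": 0.3, "carb_c": 0.3})
    weights = {"protein_c": 1.0, "lipid_c": 1.0, "carb_c": 1.0}
    out = rescale_biomass(model, 0.4, weights, {"protein_c"})
    coeffs = {m.id: -c for m, c in out.reactions.BIOMASS.metabolites.items()}
    assert coeffs == pytest.approx({"protein_c": 0.4, "lipid_c": 0.3, "carb_c": 0.3})


@pytest.mark.parametrize("C", [0.05, 0.2, 0.5, 0.9])
def test_rescale_biomass_mass_sum_invariant(toy, C):
    out = rescale_biomass(toy.model, C, toy.biomass_weights, toy.protein_components)
    total = sum(
        -c * toy.biomass_weights[m.id]
        for m, c in out.reactions.BIOMASS.metabolites.items()
        if m.id in toy.biomass_weights
    )
    assert total == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize("C", [0.0, 1.0, -0.2, 1.5])
def test_rescale_biomass_domain_errors(toy, C):
    with pytest.raises(ValueError):
        rescale_biomass(toy.model, C, toy.biomass_weights, toy.protein_components)


# ---------------------------------------------------------------------------
# MILP: closed forms and structural properties
# ---------------------------------------------------------------------------


def _micro(reactions, objective, gprs=None, bounds=None) -> cobra.Model:
    """Tiny model builder: reactions as {id: {met: coeff}}."""
    model = cobra.Model("micro")
    mets = {m for st in reactions.values() for m in st}
    model.add_metabolites([cobra.Metabolite(m, compartment="c") for m in sorted(mets)])
    for rid, st in reactions.items():
        lo, hi = (bounds or {}).get(rid, (0.0, 1000.0))
        rxn = cobra.Reaction(rid, lower_bound=lo, upper_bound=hi)
        model.add_reactions([rxn])
        rxn.add_metabolites({model.metabolites.get_by_id(m): c for m, c in st.items()})
        if gprs and rid in gprs:
            rxn.gene_reaction_rule = gprs[rid]
    model.objective = objective
    return model


def test_single_enzyme_closed_form():
    """E^g <= C/MW = 0.001, so v <= 0.001 * 3600 = 3.6."""
    model = _micro(
        {"EX_a": {"a": -1}, "R": {"a": -1, "b": 1}, "EX_b": {"b": -1}},
        objective="R",
        gprs={"R": "g"},
        bounds={"EX_a": (-100.0, 1000.0)},
    )
    enz = EnzymeConstraintSet(kcat={"R": 3600.0}, mw={"g": 1.0}, C=0.001)
    sol = solve_emoment(build_emoment(model, enz))
    assert sol.growth == pytest.approx(3.6, abs=1e-9)


def test_promiscuous_gene_allocations_sum_to_abundance():
    """One gene on two reactions: allocations share E^g; flux <= kcat*C/MW."""
    model = _micro(
        {
            "EX_a": {"a": -1},
            "R1": {"a": -1, "d": 1},
            "R2": {"a": -1, "d": 1},
            "EX_d": {"d": -1},
        },
        objective="EX_d",
        gprs={"R1": "g", "R2": "g"},
        bounds={"EX_a": (-100.0, 1000.0)},
    )
    enz = EnzymeConstraintSet(kcat={"R1": 3600.0, "R2": 3600.0}, mw={"g": 2.0}, C=0.01)
    problem = build_emoment(model, enz)
    sol = solve_emoment(problem)
    # total catalysis bounded by the single gene's abundance
    assert sol.growth == pytest.approx(3600.0 * 0.01 / 2.0, abs=1e-9)
    assert (
        sol.reaction_enzymes["R1"] + sol.reaction_enzymes["R2"]
        <= sol.gene_abundances["g"] + 1e-9
    )


def test_complex_limited_by_scarcest_subunit():
    """AND complex: E^r cannot exceed either member's allocation."""
    model = _micro(
        {"EX_a": {"a": -1}, "R": {"a": -1, "b": 1}, "EX_b": {"b": -1}},
        objective="R",
        gprs={"R": "g1 and g2"},
        bounds={"EX_a": (-100.0, 1000.0)},
    )
    # g2 is very heavy: the complex is limited by how much g2 fits in C
    enz = EnzymeConstraintSet(kcat={"R": 3600.0}, mw={"g1": 1.0, "g2": 99.0}, C=0.1)
    sol = solve_emoment(build_emoment(model, enz))
    assert sol.growth == pytest.approx(3600.0 * 0.1 / 100.0, abs=1e-8)


def test_gene_forced_off_blocks_its_reactions(emoment_problem):
    """y = 0 for the lipid-synthesis gene removes growth entirely."""
    y_idx = emoment_problem.y_index["gLIP"]
    sol = solve_emoment(emoment_problem, extra_rows=[({y_idx: 1.0}, 0.0, 0.0)])
    assert sol.growth == pytest.approx(0.0, abs=1e-9)
    assert sol.fluxes["LIPSYN"] == pytest.approx(0.0, abs=1e-9)


def test_generous_budget_recovers_plain_fba(split_setup, toy):
    split, assignment = split_setup
    enz = EnzymeConstraintSet(kcat=assignment.values, mw=toy.mw, C=10.0 - 1e-9)
    # beta must allow the abundances a generous budget implies
    enz.beta = 1.0
    sol = solve_emoment(build_emoment(split.model, enz))
    assert sol.growth == pytest.approx(fba(split.model).objective_value, abs=1e-6)


def test_zero_budget_zero_growth(split_setup, toy):
    split, assignment = split_setup
    enz = EnzymeConstraintSet(kcat=assignment.values, mw=toy.mw, C=0.0)
    sol = solve_emoment(build_emoment(split.model, enz))
    assert sol.growth == pytest.approx(0.0, abs=1e-9)


def test_growth_monotone_in_protein_budget(split_setup, toy):
    split, assignment = split_setup
    growths = []
    for C in (0.005, 0.01, 0.02, 0.04, 0.08):
        enz = EnzymeConstraintSet(kcat=assignment.values, mw=toy.mw, C=C)
        growths.append(solve_emoment(build_emoment(split.model, enz)).growth)
    assert all(b >= a - 1e-9 for a, b in zip(growths, growths[1:]))


def test_growth_linear_in_budget_when_only_crowding_binds():
    model = _micro(
        {
            "EX_a": {"a": -1},
            "R1": {"a": -1, "b": 1},
            "R2": {"b": -1, "c": 1},
            "EX_c": {"c": -1},
        },
        objective="EX_c",
        gprs={"R1": "g1", "R2": "g2"},
        bounds={"EX_a": (-1e6, 1e6)},
    )
    kcat = {"R1": 1000.0, "R2": 4000.0}
    mw = {"g1": 10.0, "g2": 30.0}
    growths = {}
    for C in (0.01, 0.02):
        enz = EnzymeConstraintSet(kcat=kcat, mw=mw, C=C)
        growths[C] = solve_emoment(build_emoment(model, enz)).growth
    assert growths[0.02] == pytest.approx(2 * growths[0.01], rel=1e-9)
    # closed form: v * (mw1/kcat1 + mw2/kcat2) = C
    expected = 0.01 / (10.0 / 1000.0 + 30.0 / 4000.0)
    assert growths[0.01] == pytest.approx(expected, rel=1e-9)


def test_emoment_never_exceeds_fba(emoment_problem, split_setup):
    split, _ = split_setup
    assert solve_emoment(emoment_problem).growth <= fba(split.model).objective_value + 1e-9


def test_missing_molecular_weight_is_a_build_error(split_setup):
    split, assignment = split_setup
    enz = EnzymeConstraintSet(kcat=assignment.values, mw={"gGLY": 100.0}, C=0.05)
    with pytest.raises(ValueError, match="molecular weight"):
        build_emoment(split.model, enz)


# ---------------------------------------------------------------------------
# Abundance variability and sampling
# ---------------------------------------------------------------------------


def test_abundance_variability_relaxation_nesting(emoment_problem):
    tight = abundance_variability(emoment_problem, fraction=1.0)
    loose = abundance_variability(emoment_problem, fraction=0.99)
    assert (loose["minimum"] <= tight["minimum"] + 1e-9).all()
    assert (loose["maximum"] >= tight["maximum"] - 1e-9).all()
    optimum = solve_emoment(emoment_problem)
    for gene, eg in optimum.gene_abundances.items():
        assert loose.loc[gene, "minimum"] - 1e-8 <= eg <= loose.loc[gene, "maximum"] + 1e-8


def test_sample_abundances_seed_reproducible(emoment_problem):
    a = sample_abundances(emoment_problem, n=5, fraction=0.99, seed=11)
    b = sample_abundances(emoment_problem, n=5, fraction=0.99, seed=11)
    assert a.samples.equals(b.samples)
    c = sample_abundances(emoment_problem, n=5, fraction=0.99, seed=12)
    assert not a.samples.equals(c.samples)


def test_sample_abundances_respect_constraints(emoment_problem, toy):
    ranges = abundance_variability(emoment_problem, fraction=0.99)
    out = sample_abundances(emoment_problem, n=10, fraction=0.99, seed=5, ranges=ranges)
    assert out.failures == 0
    mw = pd.Series({g: toy.mw[g] for g in out.samples.columns})
    crowding = (out.samples * mw).sum(axis=1)
    assert (crowding <= emoment_problem.enz.C + 1e-6).all()
    for gene in out.samples.columns:
        assert (out.samples[gene] >= ranges.loc[gene, "minimum"] - 1e-6).all()
        assert (out.samples[gene] <= ranges.loc[gene, "maximum"] + 1e-6).all()


def test_sample_abundances_degenerate_ranges_collapse():
    model = _micro(
        {"EX_a": {"a": -1}, "R": {"a": -1, "b": 1}, "EX_b": {"b": -1}},
        objective="R",
        gprs={"R": "g"},
        bounds={"EX_a": (-100.0, 1000.0)},
    )
    enz = EnzymeConstraintSet(kcat={"R": 3600.0}, mw={"g": 1.0}, C=0.001)
    problem = build_emoment(model, enz)
    out = sample_abundances(problem, n=4, fraction=1.0, seed=0)
    # at the full optimum the single abundance is pinned to C/MW
    assert np.allclose(out.samples["g"], 0.001, atol=1e-9)


def test_l2_norm_not_available(emoment_problem):
    with pytest.raises(NotImplementedError):
        sample_abundances(emoment_problem, n=1, norm="l2")


# ---------------------------------------------------------------------------
# Condition panel and pool split
# ---------------------------------------------------------------------------


def _conditions(toy, concentrations, C):
    kin = toy.carbon_kinetics["glc_e"]
    cap = toy.ground_truth.min_palmitate_uptake
    return [
        ConditionSpec(f"glc_{int(s)}", "glc_e", s, C, kin, toy.palmitate_key, cap)
        for s in concentrations
    ]


def test_panel_growth_monotone_in_concentration(toy):
    """Fixed C: a higher concentration only relaxes the uptake bound."""
    result = simulate_condition_panel(
        toy.model,
        toy.kcat_table,
        toy.mw,
        _conditions(toy, (10.0, 100.0, 1000.0), C=0.03),
        base_medium={"nh4_e": 100.0},
        biomass_weights=toy.biomass_weights,
        protein_components=toy.protein_components,
    )
    growth = result.table["growth"].to_numpy()
    assert np.all(np.diff(growth) >= -1e-9)
    assert (result.table["growth"] <= result.table["growth_fba"] + 1e-9).all()


def test_panel_palmitate_cap_is_a_restriction(toy):
    kin = toy.carbon_kinetics["glc_e"]
    capped = ConditionSpec("capped", "glc_e", 100.0, 0.03, kin, toy.palmitate_key,
                           toy.ground_truth.min_palmitate_uptake)
    uncapped = ConditionSpec("uncapped", "glc_e", 100.0, 0.03, kin, toy.palmitate_key, 1000.0)
    result = simulate_condition_panel(
        toy.model, toy.kcat_table, toy.mw, [capped, uncapped],
        base_medium={"nh4_e": 100.0},
        biomass_weights=toy.biomass_weights,
        protein_components=toy.protein_components,
    )
    assert result.table.loc["uncapped", "growth"] >= result.table.loc["capped", "growth"] - 1e-9


def test_condition_spec_validation(toy):
    kin = toy.carbon_kinetics["glc_e"]
    with pytest.raises(ValueError):
        ConditionSpec("bad", "glc_e", 10.0, 1.5, kin, "pmt_e", 1.0)
    with pytest.raises(ValueError):
        ConditionSpec("bad", "glc_e", -1.0, 0.1, kin, "pmt_e", 1.0)


def test_protein_pool_split_reference_and_benefit(toy):
    result = protein_pool_split(
        toy.model,
        toy.kcat_table,
        toy.mw,
        C=0.03,
        peroxisomal_genes=toy.peroxisomal_genes,
        alpha_grid=[0.0, 0.2, 0.4],
        myristate_key=toy.myristate_key,
        myristate_uptake=5.0,
        base_medium=toy.default_medium,
    )
    table = result.table
    # no peroxisomal budget -> the myristate pathway cannot be expressed
    assert table.loc[0.0, "Z"] == pytest.approx(1.0, abs=1e-6)
    # planted beta-oxidation benefit appears at positive pool ratios
    assert (table.loc[[0.2, 0.4], "Z"] > 1.0).any()
    # the reference growth can only shrink as budget is diverted to the pool
    ref = table["growth_without_myristate"].to_numpy()
    assert np.all(np.diff(ref) <= 1e-9)


def test_protein_pool_split_requires_peroxisomal_genes(toy):
    with pytest.raises(ValueError):
        protein_pool_split(
            toy.model, toy.kcat_table, toy.mw, 0.03, set(), [0.0],
            toy.myristate_key, 5.0, base_medium=toy.default_medium,
        )


# ---------------------------------------------------------------------------
# Plasticity CV
# ---------------------------------------------------------------------------


def test_plasticity_cv_values_and_invariance():
    a = pd.DataFrame({"x": [1.0, 1.0], "y": [1.0, 1.0], "z": [0.0, 0.0]})
    b = pd.DataFrame({"x": [3.0, 3.0], "y": [1.0, 1.0], "z": [0.0, 0.0]})
    cv = plasticity_cv({"c1": a, "c2": b})
    assert cv["x"] == pytest.approx(np.std([1.0, 3.0], ddof=1) / 2.0)  # 0.7071...
    assert cv["y"] == pytest.approx(0.0)
    assert np.isnan(cv["z"])  # zero mean -> undefined
    doubled = plasticity_cv({"c1": 2 * a, "c2": 2 * b})
    assert doubled["x"] == pytest.approx(cv["x"])  # scale invariance


def test_plasticity_cv_needs_two_conditions():
    with pytest.raises(ValueError):
        plasticity_cv({"only": pd.DataFrame({"x": [1.0]})})
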