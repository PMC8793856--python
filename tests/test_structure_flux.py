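"""Transcript integration, flux sampling and A_w differential calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import chain_model
from oracles import aw_bruteforce
from ecgem.structure_flux import (
    audit_flux_samples,
    differential_reactions,
    effect_size_aw,
    effect_size_table,
    flux_variability_99,
    growth_with_protein_band,
    run_structure_comparison,
    sample_fluxes,
    structure_growth,
    transcript_reaction_bounds,
    transcript_to_protein,
)
from ecgem.synthetic_data import (
    generate_structure_transcripts,
    structure_model_and_kcats,
)


@pytest.fixture(scope="module")
def structure_setup(toy):
    model, assignment = structure_model_and_kcats(toy)
    return model, assignment.values


# ---------------------------------------------------------------------------
# Transcripts -> protein equivalents
# ---------------------------------------------------------------------------


def test_transcript_to_protein_arithmetic():
    profile = transcript_to_protein(
        {"a": 2.0, "b": 3.0, "c": 5.0}, C=0.1, mw={"a": 1.0, "b": 1.0, "c": 1.0}
    )
    assert profile.normalized.sum() == pytest.approx(1.0, abs=1e-12)
    assert profile.protein_equivalents.to_dict() == pytest.approx(
        {"a": 0.02, "b": 0.03, "c": 0.05}
    )


def test_transcript_to_protein_single_gene():
    profile = transcript_to_protein({"a": 7.0}, C=0.2, mw={"a": 4.0})
    assert profile.normalized["a"] == 1.0
    assert profile.protein_equivalents["a"] == pytest.approx(0.05)


def test_transcript_mass_identity_random_profiles():
    rng = np.random.default_rng(3)
    for _ in range(20):
        genes = [f"g{i}" for i in range(int(rng.integers(2, 12)))]
        counts = {g: float(rng.uniform(0, 1000)) for g in genes}
        counts[genes[0]] += 1.0  # keep the total positive
        mw = {g: float(rng.uniform(10, 300)) for g in genes}
        C = float(rng.uniform(0.01, 0.3))
        profile = transcript_to_protein(counts, C, mw)
        assert profile.normalized.sum() == pytest.approx(1.0, abs=1e-9)
        mass = sum(profile.protein_equivalents[g] * mw[g] for g in genes)
        assert mass == pytest.approx(C, abs=1e-6)


def test_transcript_to_protein_errors():
    with pytest.raises(ValueError, match="positive"):
        transcript_to_protein({"a": 0.0}, 0.1, {"a": 1.0})
    with pytest.raises(ValueError, match="weights"):
        transcript_to_protein({"a": 1.0, "b": 1.0}, 0.1, {"a": 1.0})


# ---------------------------------------------------------------------------
# Reaction bounds from GPR rules
# ---------------------------------------------------------------------------


def test_transcript_bounds_complex_takes_minimum(structure_setup, toy):
    model, kcats = structure_setup
    counts = {g.id: 100.0 for g in toy.model.genes}
    counts["gAA1"], counts["gAA2"] = 10.0, 20.0
    profile = transcript_to_protein(counts, 0.106, toy.mw)
    bounds = transcript_reaction_bounds(model, profile, kcats)
    expected = kcats["AASYN"] * min(
        profile.protein_equivalents["gAA1"], profile.protein_equivalents["gAA2"]
    )
    assert bounds["AASYN"] == pytest.approx(expected)


def test_transcript_bounds_isozyme_ignores_zero_member(structure_setup, toy):
    model, kcats = structure_setup
    counts = {g.id: 100.0 for g in toy.model.genes}
    counts["gPS1"] = 0.0
    profile = transcript_to_protein(counts, 0.106, toy.mw)
    bounds = transcript_reaction_bounds(model, profile, kcats)
    assert bounds["PROTSYN"] == pytest.approx(
        kcats["PROTSYN"] * profile.protein_equivalents["gPS2"]
    )
    # reactions without a GPR are untouched
    assert "T_NH4" not in bounds.index
    assert "BIOMASS" not in bounds.index


def test_all_zero_transcripts_abolish_growth(structure_setup, toy):
    model, kcats = structure_setup
    counts = {g.id: 1.0 for g in toy.model.genes}
    for g in ("tPMT",):  # zero transcript for the essential lipid transporter
        counts[g] = 0.0
    profile = transcript_to_protein(counts, 0.106, toy.mw)
    bounds = transcript_reaction_bounds(model, profile, kcats)
    assert structure_growth(model, bounds).objective_value == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Growth under structure bounds
# ---------------------------------------------------------------------------


def test_doubled_bounds_never_reduce_growth(structure_setup, toy):
    model, kcats = structure_setup
    counts = {g.id: 50.0 for g in toy.model.genes}
    profile = transcript_to_protein(counts, 0.106, toy.mw)
    bounds = transcript_reaction_bounds(model, profile, kcats)
    base = structure_growth(model, bounds).objective_value
    relaxed = structure_growth(model, 2.0 * bounds).objective_value
    assert relaxed >= base - 1e-9


def test_boosted_growth_pathway_raises_growth(toy):
    """Planting the fold on the palmitate transporter raises ARB growth."""
    model, assignment = structure_model_and_kcats(toy)
    tr = generate_structure_transcripts(toy, seed=2, planted=["T_PMT"], fold=10.0)
    growths = {}
    for structure, counts in tr.counts.items():
        profile = transcript_to_protein(counts, 0.106, toy.mw)
        bounds = transcript_reaction_bounds(model, profile, assignment.values)
        growths[structure] = structure_growth(model, bounds).objective_value
    assert growths["ARB"] > growths["ERM"] + 1e-6
    assert growths["IRM"] > growths["ERM"] + 1e-6


def test_growth_with_protein_band_ordering(structure_setup, toy):
    model, kcats = structure_setup
    counts = {g.id: 50.0 for g in toy.model.genes}
    band = growth_with_protein_band(model, counts, toy.mw, kcats, C=0.106, sigma=0.02)
    assert band["growth_lo"] <= band["growth"] <= band["growth_hi"]


# ---------------------------------------------------------------------------
# 99%-optimum variability and sampling
# ---------------------------------------------------------------------------


def test_flux_variability_99_contains_full_optimum(structure_setup, toy):
    model, kcats = structure_setup
    counts = {g.id: 50.0 for g in toy.model.genes}
    profile = transcript_to_protein(counts, 0.106, toy.mw)
    bounds = transcript_reaction_bounds(model, profile, kcats)
    loose = flux_variability_99(model, bounds, fraction=0.99)
    tight = flux_variability_99(model, bounds, fraction=1.0)
    assert (loose["minimum"] <= tight["minimum"] + 1e-9).all()
    assert (loose["maximum"] >= tight["maximum"] - 1e-9).all()


def test_sample_fluxes_deterministic_and_feasible(structure_setup, toy):
    model, kcats = structure_setup
    counts = {g.id: 50.0 for g in toy.model.genes}
    profile = transcript_to_protein(counts, 0.106, toy.mw)
    bounds = transcript_reaction_bounds(model, profile, kcats)
    a = sample_fluxes(model, bounds, n=15, seed=4)
    b = sample_fluxes(model, bounds, n=15, seed=4)
    assert a.samples.equals(b.samples)
    assert a.failures == 0
    assert audit_flux_samples(model, a, bounds) <= 1e-6


def test_sample_fluxes_degenerate_box_collapses():
    model = chain_model()
    samples = sample_fluxes(model, {}, n=6, seed=0, fraction=1.0)
    # a unique optimum leaves no sampling freedom
    assert (samples.samples.nunique() == 1).all()


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "p, q, expected",
    [
        ([5, 6, 7], [1, 2, 3], 1.0),  # complete separation
        ([2, 2], [2, 2], 0.5),  # all ties
        ([1, 2, 3], [2, 2, 2], 0.5),  # (3 wins + 1.5 tie-credit) / 9
    ],
)
def test_effect_size_known_values(p, q, expected):
    assert effect_size_aw(p, q) == pytest.approx(expected, abs=1e-12)


def test_effect_size_empty_vector_rejected():
    with pytest.raises(ValueError):
        effect_size_aw([], [1.0])


@settings(max_examples=150, derandomize=True)
@given(
    p=st.lists(st.integers(-5, 5), min_size=1, max_size=40),
    q=st.lists(st.integers(-5, 5), min_size=1, max_size=40),
)
def test_effect_size_matches_bruteforce_and_symmetry(p, q):
    """Rank-based A_w equals exhaustive pair counting; A(p,q)+A(q,p)=1."""
    aw = effect_size_aw(p, q)
    assert aw == pytest.approx(aw_bruteforce(p, q), abs=1e-12)
    assert aw + effect_size_aw(q, p) == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= aw <= 1.0


def test_effect_size_table_requires_matching_columns():
    a = pd.DataFrame({"r1": [1.0], "r2": [2.0]})
    b = pd.DataFrame({"r1": [1.0], "r3": [2.0]})
    with pytest.raises(ValueError, match="mismatch"):
        effect_size_table(a, b)


# ---------------------------------------------------------------------------
# Differential calling
# ---------------------------------------------------------------------------


def test_identical_samples_produce_no_calls():
    rng = np.random.default_rng(0)
    samples = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    result = differential_reactions(samples, samples.copy())
    assert all(not calls for calls in result.calls.values())
    assert (result.aw == 0.5).all()


def test_threshold_monotonicity_and_tally():
    rng = np.random.default_rng(1)
    a = pd.DataFrame({"r1": rng.normal(0, 1, 80), "r2": rng.normal(0, 1, 80)})
    b = pd.DataFrame({"r1": rng.normal(3, 1, 80), "r2": rng.normal(0.3, 1, 80)})
    result = differential_reactions(a, b, subsystems={"r1": "lipid", "r2": "amino"})
    assert set(result.calls[0.8]) <= set(result.calls[0.7]) <= set(result.calls[0.6])
    assert "r1" in result.calls[0.8]
    assert result.subsystem_tally[0.8]["lipid"] == 1


# ---------------------------------------------------------------------------
# End-to-end recovery (scaled down; the acceptance suite runs n=500)
# ---------------------------------------------------------------------------


def test_recovery_of_planted_differential_reactions(structure_setup, toy):
    model, kcats = structure_setup
    tr = generate_structure_transcripts(toy, seed=0, fold=10.0)
    cmp = run_structure_comparison(
        model, tr.counts, kcats, toy.mw, n=120, seed=1, subsystems=toy.subsystems
    )
    # growth is lipid-limited, hence identical across structures here
    assert cmp.growth.nunique() == 1
    chain = set(toy.ground_truth.planted_differential) | set(toy.ground_truth.planted_coupled)
    for pair in (("ERM", "IRM"), ("ERM", "ARB")):
        result = cmp.pairwise[pair]
        extremity = np.maximum(result.aw, 1 - result.aw)
        assert extremity["OVF"] >= 0.8  # planted reaction recovered
        false_calls = [r for r in result.calls[0.6] if r.removesuffix("_rev") not in chain]
        assert false_calls == []


def test_null_run_produces_no_calls(structure_setup, toy):
    model, kcats = structure_setup
    tr = generate_structure_transcripts(toy, seed=0, fold=1.0)
    cmp = run_structure_comparison(model, tr.counts, kcats, toy.mw, n=120, seed=1)
    for result in cmp.pairwise.values():
        assert result.calls[0.6] == []
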