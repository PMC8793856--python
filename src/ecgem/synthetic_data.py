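"""Synthetic toy models and data sets with known ground truth.

Every pipeline stage in this package can be exercised without downloads:
this module emits a small compartmentalized toy GEM shaped like an
arbuscular-mycorrhizal-fungus metabolism (obligate host-supplied lipid,
peroxisomal beta-oxidation branch, complexes, isozymes and a promiscuous
gene), a kcat parameter table with planted matching/pruning/fallback
cases, a 4-carbon-source x 3-concentration condition design with
Michaelis-Menten transporter kinetics, and three-structure transcript
profiles with planted differential reactions.  All ground truths are
re-verified at generation time by an independent LP solve (HiGHS via
``scipy.optimize.linprog``, separate from the cobrapy/GLPK analysis path).

The toy network (default spec)::

    sugars (glc/frc/raf/mel) --transport--> hexose --> carbon skeleton + ATP
    palmitate (obligatory)   --transport--> lipid precursor --> lipid
    myristate --> peroxisome --> beta-oxidation --> ATP
    carbon skeleton + NH4 + ATP --> amino acids --> protein
    biomass = protein + lipid + carbohydrate + ATP (mass-normalized to 1 g/gDW)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import cobra
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linprog

from .emoment import (
    ConditionSpec,
    EnzymeConstraintSet,
    TransporterKinetics,
    simulate_condition_panel,
    uptake_bound,
)
from .kcat_assignment import assign_kcats
from .model_core import apply_medium, split_reversible, stoichiometric_matrix, write_sbml

#: molecular weights of the biomass pseudometabolites, g mmol^-1
BIOMASS_COMPONENT_MW = {"protein_c": 0.100, "lipid_c": 0.256, "carb_c": 0.162}

__all__ = [
    "ToyModelSpec",
    "GroundTruth",
    "ToyDataset",
    "ConditionDesign",
    "StructureTranscripts",
    "generate_toy_model",
    "generate_kcat_table",
    "generate_condition_design",
    "generate_structure_transcripts",
    "generate_random_micro_model",
    "structure_medium",
    "structure_model_and_kcats",
    "write_toy_dataset",
]


# ---------------------------------------------------------------------------
# Specs and bundles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of the generated toy GEM.

    The default emits ~30 reactions, ~19 genes and 3 compartments — large
    enough to exercise every GPR pattern (complex, isozymes, promiscuous
    gene), small enough for enumeration oracles.
    """

    seed: int = 0
    n_carbon_branches: int = 4
    protein_fraction: float = 0.40
    lipid_fraction: float = 0.35
    carbohydrate_fraction: float = 0.25
    gam_atp: float = 20.0
    mw_range: tuple[float, float] = (120.0, 280.0)

    def __post_init__(self) -> None:
        total = self.protein_fraction + self.lipid_fraction + self.carbohydrate_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("biomass mass fractions must sum to 1")
        if min(self.protein_fraction, self.lipid_fraction, self.carbohydrate_fraction) <= 0:
            raise ValueError("biomass mass fractions must be positive")
        if not 1 <= self.n_carbon_branches <= 4:
            raise ValueError("toy model needs between 1 and 4 carbon branches")


@dataclass
class GroundTruth:
    """Quantities planted in (and re-verified against) a generated dataset.

    ``planted_coupled`` lists the gene-less carrier reactions that are
    stoichiometrically forced to follow the planted differential reactions
    (the rest of their dedicated substrate chain); they shift whenever the
    planted reactions do.
    """

    fba_optimum: float
    min_palmitate_uptake: float
    planted_differential: list[str]
    expected_kcats: dict[str, tuple[float, str]]
    planted_coupled: list[str] = field(default_factory=list)
    condition_growth: dict[str, float] = field(default_factory=dict)


@dataclass
class ToyDataset:
    """A toy GEM plus every sidecar the pipeline consumes."""

    model: cobra.Model  # medium not applied
    default_medium: dict[str, float]
    kcat_table: pd.DataFrame
    mw: dict[str, float]
    biomass_weights: dict[str, float]
    protein_components: set[str]
    peroxisomal_genes: set[str]
    palmitate_key: str
    myristate_key: str
    carbon_kinetics: dict[str, TransporterKinetics]  # medium key -> kinetics
    subsystems: dict[str, str]
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Independent LP oracle (generation-time validation)
# ---------------------------------------------------------------------------


def _lp_optimize(
    model: cobra.Model,
    objective_id: str,
    maximize: bool = True,
    growth_floor: tuple[str, float] | None = None,
) -> float:
    """Plain LP on the model arrays via HiGHS, independent of cobrapy's solver."""
    rxn_ids = [r.id for r in model.reactions]
    S = stoichiometric_matrix(model)
    lb = [r.lower_bound for r in model.reactions]
    ub = [r.upper_bound for r in model.reactions]
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = -1.0 if maximize else 1.0
    A_ub = None
    b_ub = None
    if growth_floor is not None:
        floor_id, floor = growth_floor
        row = np.zeros(len(rxn_ids))
        row[rxn_ids.index(floor_id)] = -1.0
        A_ub = sp.csr_matrix(row)
        b_ub = np.array([-floor])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"generation-time LP failed with status {res.status}")
    return -res.fun if maximize else res.fun


# ---------------------------------------------------------------------------
# Toy model
# ---------------------------------------------------------------------------

_CARBON_BRANCHES = (
    # (source tag, transporter id, gene, hexose yield per transport flux)
    ("glc", "T_GLC", "tGLC", 1.0),
    ("frc", "T_FRC", "tFRC", 1.0),
    ("raf", "T_RAF", "tRAF", 2.0),
    ("mel", "T_MEL", "tMEL", 2.0),
)

_DEFAULT_KINETICS = {
    "glc_e": TransporterKinetics(11.0, 9.0, "glc_e"),
    "frc_e": TransporterKinetics(9.0, 14.0, "frc_e"),
    "raf_e": TransporterKinetics(3.5, 30.0, "raf_e"),
    "mel_e": TransporterKinetics(4.2, 22.0, "mel_e"),
}


def _met(model: cobra.Model, mid: str, name: str, compartment: str) -> cobra.Metabolite:
    met = cobra.Metabolite(mid, name=name, compartment=compartment)
    model.add_metabolites([met])
    return met


def _rxn(
    model: cobra.Model,
    rid: str,
    stoich: Mapping[str, float],
    bounds: tuple[float, float] = (0.0, 1000.0),
    gpr: str = "",
    ec: Sequence[str] = (),
    subsystem: str = "",
) -> cobra.Reaction:
    rxn = cobra.Reaction(rid, lower_bound=bounds[0], upper_bound=bounds[1])
    model.add_reactions([rxn])
    rxn.add_metabolites({model.metabolites.get_by_id(m): c for m, c in stoich.items()})
    if gpr:
        rxn.gene_reaction_rule = gpr
    if ec:
        rxn.annotation["ec-code"] = list(ec)
    rxn.subsystem = subsystem
    return rxn


def generate_toy_model(
    spec: ToyModelSpec | None = None, with_sbc_loop: bool = False
) -> ToyDataset:
    """Generate the toy GEM, its kcat table, and all sidecars.

    The planted structure: growth strictly requires palmitate uptake (the
    host-supplied lipid), a myristate branch feeds ATP through a
    peroxisomal complex, AASYN is an AND-complex, PROTSYN an isozyme pair,
    and gene ``gPROM`` promiscuously catalyzes two reactions.  With
    ``with_sbc_loop`` a three-reaction internal loop with one reversible
    member is added (for cycle-detection tests).  The FBA optimum and the
    minimal palmitate uptake at optimal growth are recomputed by an
    independent LP at generation time.
    """
    spec = spec or ToyModelSpec()
    rng = np.random.default_rng(spec.seed)
    model = cobra.Model("toy_amf")

    # metabolites
    _met(model, "hex_c", "D-hexose", "c")
    _met(model, "hex2_c", "D-hexose (isomer)", "c")
    _met(model, "cskel_c", "carbon skeleton", "c")
    _met(model, "atp_c", "ATP equivalent", "c")
    _met(model, "aa_c", "amino acid pool", "c")
    _met(model, "protein_c", "protein", "c")
    _met(model, "lipid_c", "lipid", "c")
    _met(model, "carb_c", "storage carbohydrate", "c")
    _met(model, "pmt_c", "palmitate", "c")
    _met(model, "nh4_c", "ammonium", "c")
    _met(model, "dead_c", "dead-end metabolite", "c")
    _met(model, "waste_c", "overflow product", "c")
    _met(model, "myr_p", "myristate", "p")
    _met(model, "pmt_e", "palmitate", "e")
    _met(model, "myr_e", "myristate", "e")
    _met(model, "nh4_e", "ammonium", "e")
    _met(model, "waste_e", "overflow product", "e")
    _met(model, "xyl_e", "D-xylose", "e")
    _met(model, "xyl_c", "D-xylose", "c")
    _met(model, "ovf_e", "xylitol", "e")

    branches = _CARBON_BRANCHES[: spec.n_carbon_branches]
    for tag, _tid, _gene, _yield in branches:
        _met(model, f"{tag}_e", tag, "e")

    # exchanges (uptake closed until a medium is applied) and sinks
    for tag, *_ in branches:
        _rxn(model, f"EX_{tag}_e", {f"{tag}_e": -1}, subsystem="Exchange")
    _rxn(model, "EX_pmt_e", {"pmt_e": -1}, subsystem="Exchange")
    _rxn(model, "EX_myr_e", {"myr_e": -1}, subsystem="Exchange")
    _rxn(model, "EX_nh4_e", {"nh4_e": -1}, subsystem="Exchange")
    _rxn(model, "EX_waste_e", {"waste_e": -1}, subsystem="Exchange")
    _rxn(model, "EX_xyl_e", {"xyl_e": -1}, subsystem="Exchange")
    _rxn(model, "EX_ovf_e", {"ovf_e": -1}, subsystem="Exchange")
    _rxn(model, "SK_atp_c", {"atp_c": -1}, subsystem="Sink")

    # transport
    for tag, tid, gene, hex_yield in branches:
        _rxn(model, tid, {f"{tag}_e": -1, "hex_c": hex_yield}, gpr=gene, subsystem="Transport")
    _rxn(model, "T_PMT", {"pmt_e": -1, "pmt_c": 1}, gpr="tPMT", subsystem="Transport")
    _rxn(model, "T_MYR", {"myr_e": -1, "myr_p": 1}, gpr="tMYR", subsystem="Transport")
    _rxn(model, "T_NH4", {"nh4_e": -1, "nh4_c": 1}, subsystem="Transport")
    _rxn(model, "T_WASTE", {"waste_c": -1, "waste_e": 1}, subsystem="Transport")

    # core metabolism
    _rxn(
        model, "GLYC", {"hex_c": -1, "cskel_c": 1, "atp_c": 2},
        gpr="gGLY", ec=["2.7.1.1"], subsystem="Carbohydrate metabolism",
    )
    _rxn(
        model, "ISO", {"hex_c": -1, "hex2_c": 1}, bounds=(-100.0, 100.0),
        gpr="gISO", ec=["5.3.1.9"], subsystem="Carbohydrate metabolism",
    )
    _rxn(
        model, "ALT", {"hex2_c": -1, "cskel_c": 1, "atp_c": 1},
        gpr="gALT", ec=["1.1.1.1"], subsystem="Carbohydrate metabolism",
    )
    _rxn(
        model, "OXID", {"cskel_c": -1, "atp_c": 3, "waste_c": 1},
        gpr="gOX", ec=["1.3.99.33"], subsystem="Energy metabolism",
    )
    _rxn(
        model, "AASYN", {"cskel_c": -1, "nh4_c": -1, "atp_c": -1, "aa_c": 1},
        gpr="gAA1 and gAA2", ec=["6.3.1.2"], subsystem="Amino acid metabolism",
    )
    _rxn(
        model, "PROTSYN", {"aa_c": -2, "atp_c": -2, "protein_c": 1},
        gpr="gPS1 or gPS2", ec=["6.1.1.1"], subsystem="Amino acid metabolism",
    )
    _rxn(
        model, "LIPSYN", {"pmt_c": -1, "atp_c": -1, "lipid_c": 1},
        gpr="gLIP", ec=["2.3.1.86"], subsystem="Lipid metabolism",
    )
    _rxn(
        model, "CARBSYN", {"cskel_c": -1, "atp_c": -1, "carb_c": 1},
        gpr="gPROM", ec=["2.4.1.1"], subsystem="Carbohydrate metabolism",
    )
    _rxn(
        model, "WASTE1", {"cskel_c": -1, "waste_c": 1},
        gpr="gPROM", ec=["2.4.1.1"], subsystem="Overflow",
    )
    # dedicated side-substrate chain: xylose -> secreted xylitol.  OVF is the
    # only enzymatic step, so its transcript bound is the chain's bottleneck
    # and planted fold changes act on it without touching the growth pathway.
    _rxn(model, "T_XYL", {"xyl_e": -1, "xyl_c": 1}, subsystem="Transport")
    _rxn(
        model, "OVF", {"xyl_c": -1, "ovf_e": 1},
        gpr="gOV", subsystem="Overflow",
    )
    _rxn(
        model, "BOX", {"myr_p": -1, "atp_c": 4},
        gpr="gBOX1 and gBOX2", ec=["1.3.3.6"], subsystem="Peroxisomal beta-oxidation",
    )
    _rxn(model, "DEADEND", {"cskel_c": -1, "dead_c": 1}, subsystem="Misc")

    if with_sbc_loop:
        _met(model, "x1_c", "loop metabolite 1", "c")
        _met(model, "x2_c", "loop metabolite 2", "c")
        _met(model, "x3_c", "loop metabolite 3", "c")
        _rxn(model, "LOOP1", {"x1_c": -1, "x2_c": 1}, subsystem="Misc")
        _rxn(model, "LOOP2", {"x2_c": -1, "x3_c": 1}, subsystem="Misc")
        _rxn(model, "LOOP3", {"x3_c": -1, "x1_c": 1}, bounds=(-1000.0, 1000.0), subsystem="Misc")

    # mass-normalized biomass: sum(coefficient * MW) = 1 g gDW^-1
    biomass_weights = dict(BIOMASS_COMPONENT_MW)
    coeffs = {
        "protein_c": -spec.protein_fraction / biomass_weights["protein_c"],
        "lipid_c": -spec.lipid_fraction / biomass_weights["lipid_c"],
        "carb_c": -spec.carbohydrate_fraction / biomass_weights["carb_c"],
        "atp_c": -spec.gam_atp,
    }
    _rxn(model, "BIOMASS", coeffs, subsystem="Biomass")
    model.objective = "BIOMASS"

    mw = {g.id: float(rng.uniform(*spec.mw_range)) for g in sorted(model.genes, key=lambda g: g.id)}

    kcat_table, expected = generate_kcat_table(seed=spec.seed, model=model)

    default_medium = {f"{branches[0][0]}_e": 10.0, "pmt_e": 5.0, "nh4_e": 100.0}
    with_medium = apply_medium(model, default_medium)
    fba_opt = _lp_optimize(with_medium, "BIOMASS")
    if not fba_opt > 0:
        raise RuntimeError("generated toy model cannot grow on its default medium")
    # minimal palmitate uptake that still guarantees optimal growth
    max_pmt_flux = _lp_optimize(
        with_medium, "EX_pmt_e", maximize=True, growth_floor=("BIOMASS", fba_opt * (1 - 1e-9))
    )
    min_palmitate = -max_pmt_flux

    kinetics = {
        f"{tag}_e": _DEFAULT_KINETICS[f"{tag}_e"] for tag, *_ in branches
    }
    subsystems = {r.id: r.subsystem for r in model.reactions}
    ground_truth = GroundTruth(
        fba_optimum=float(fba_opt),
        min_palmitate_uptake=float(min_palmitate),
        planted_differential=["OVF"],
        expected_kcats=expected,
        planted_coupled=["EX_xyl_e", "T_XYL", "EX_ovf_e"],
    )
    return ToyDataset(
        model=model,
        default_medium=default_medium,
        kcat_table=kcat_table,
        mw=mw,
        biomass_weights=biomass_weights,
        protein_components={"protein_c"},
        peroxisomal_genes={"tMYR", "gBOX1", "gBOX2"},
        palmitate_key="pmt_e",
        myristate_key="myr_e",
        carbon_kinetics=kinetics,
        subsystems=subsystems,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# kcat table with planted rule cases
# ---------------------------------------------------------------------------

_KCAT_ROWS = [
    # duplicate full-EC records: the maximum (44) must win
    ("2.7.1.1", "", "Fungi", 18.0),
    ("2.7.1.1", "", "Fungi", 44.0),
    # substrate filter: D-hexose is the reaction's substrate name
    ("5.3.1.9", "D-hexose", "Fungi", 30.0),
    ("5.3.1.9", "L-sorbose", "Fungi", 300.0),
    ("1.1.1.1", "", "Fungi", 28.0),
    # lineage filter: the fungal record (12) must win over the larger one
    ("1.3.3.6", "", "Fungi", 12.0),
    ("1.3.3.6", "", "Metazoa", 160.0),
    # pruning: the model's EC 1.3.99.33 only matches at level 3
    ("1.3.99", "", "Fungi", 23.0),
    ("6.3.1.2", "", "Fungi", 11.0),
    ("6.1.1.1", "", "Fungi", 9.0),
    ("2.3.1.86", "", "Fungi", 7.0),
    ("2.4.1.1", "", "Fungi", 25.0),
    # decoys matching nothing in the toy model
    ("4.4.4.4", "", "Bacteria", 500.0),
    ("3.1.3.3", "octanol", "Fungi", 77.0),
]

#: median of the per-reaction matched values {44,30,28,23,12,11,9,7,25,25}
_PLANTED_MEDIAN_S = 24.0

_EXPECTED_MATCHES = {
    "GLYC": (44.0, "full-match"),
    "ISO": (30.0, "full-match"),
    "ALT": (28.0, "full-match"),
    "BOX": (12.0, "full-match"),
    "OXID": (23.0, "pruned-level-3"),
    "AASYN": (11.0, "full-match"),
    "PROTSYN": (9.0, "full-match"),
    "LIPSYN": (7.0, "full-match"),
    "CARBSYN": (25.0, "full-match"),
    "WASTE1": (25.0, "full-match"),
}


def generate_kcat_table(
    seed: int = 0, model: cobra.Model | None = None, n_rows: int | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[float, str]]]:
    """Emit a kcat table with planted rule cases and the expected outcome.

    The planted cases cover duplicate-EC maximum selection, the substrate
    filter, the fungal-lineage filter, a level-3 pruning hit, and
    median-fallback reactions (the toy transporters and the overflow
    reaction carry a GPR but no EC annotation).  The seed shuffles the row
    order only — the assignment rules are order-independent.  ``n_rows=0``
    is rejected (an empty table cannot seed any assignment).
    """
    if n_rows == 0:
        raise ValueError("an empty kcat table was requested")
    rows = list(_KCAT_ROWS)
    rng = np.random.default_rng(seed)
    rng.shuffle(rows)
    table = pd.DataFrame(rows, columns=["ec", "substrate", "lineage", "value_per_s"])
    expected: dict[str, tuple[float, str]] = dict(_EXPECTED_MATCHES)
    if model is not None:
        from .model_core import gpr_of, reaction_ec_numbers

        for rxn in model.reactions:
            if gpr_of(rxn) is not None and rxn.id not in expected:
                if not reaction_ec_numbers(rxn):
                    expected[rxn.id] = (_PLANTED_MEDIAN_S, "median-fallback")
    return table, expected


# ---------------------------------------------------------------------------
# Condition design (4 carbon sources x 3 concentrations)
# ---------------------------------------------------------------------------

# measured protein contents per (source, concentration), g gDW^-1 — chosen
# low enough that the molecular-crowding budget is the limiting resource in
# most conditions (the regime enzyme-constrained models are built for)
_CONDITION_C = {
    "glc_e": {10.0: 0.022, 100.0: 0.030, 1000.0: 0.037},
    "frc_e": {10.0: 0.019, 100.0: 0.026, 1000.0: 0.032},
    "raf_e": {10.0: 0.016, 100.0: 0.022, 1000.0: 0.027},
    "mel_e": {10.0: 0.018, 100.0: 0.024, 1000.0: 0.030},
}

CONCENTRATIONS_MM = (10.0, 100.0, 1000.0)


@dataclass
class ConditionDesign:
    """12 growth conditions plus a planted dry-weight readout.

    ``dry_weight`` is a fixed strictly-increasing transform of the
    ground-truth eMOMENT growth of each condition, so a correct pipeline
    reproduces its ranking exactly (Spearman rho = 1).
    """

    conditions: list[ConditionSpec]
    table: pd.DataFrame  # growth (ground truth), dry_weight, protein_content
    base_medium: dict[str, float]


def _dry_weight(growth: float) -> float:
    return 2.0 + 30.0 * growth + 50.0 * growth**2


def generate_condition_design(dataset: ToyDataset) -> ConditionDesign:
    """Build the 12-condition panel and its planted dry weights.

    Each condition supplies a single carbon source whose uptake bound
    follows the transporter's Michaelis-Menten kinetics at 10, 100 or
    1000 mM, a measured protein content, and the palmitate cap fixed to the
    minimal uptake at FBA-optimal growth.  The ground-truth growth per
    condition is computed by running the enzyme-constrained pipeline at
    generation time; the dry weight is a strictly monotone transform of it.
    """
    base_medium = {"nh4_e": 100.0}
    cap = dataset.ground_truth.min_palmitate_uptake
    conditions = []
    for source, kinetics in dataset.carbon_kinetics.items():
        for conc in CONCENTRATIONS_MM:
            conditions.append(
                ConditionSpec(
                    condition_id=f"{source.split('_')[0]}_{int(conc)}",
                    carbon_source=source,
                    concentration_mM=conc,
                    protein_content=_CONDITION_C[source][conc],
                    kinetics=kinetics,
                    palmitate_key=dataset.palmitate_key,
                    palmitate_cap=cap,
                )
            )
    panel = simulate_condition_panel(
        dataset.model,
        dataset.kcat_table,
        dataset.mw,
        conditions,
        base_medium=base_medium,
        biomass_weights=dataset.biomass_weights,
        protein_components=dataset.protein_components,
    )
    table = panel.table.copy()
    table["dry_weight"] = table["growth"].map(_dry_weight)
    dataset.ground_truth.condition_growth = table["growth"].to_dict()
    return ConditionDesign(conditions=conditions, table=table, base_medium=base_medium)


# ---------------------------------------------------------------------------
# Structure transcripts with planted differential reactions
# ---------------------------------------------------------------------------

#: palmitate cap for the structure experiment: small enough that growth is
#: lipid-limited, leaving every unperturbed transcript bound slack
STRUCTURE_PALMITATE_CAP = 0.08


@dataclass
class StructureTranscripts:
    """Per-structure transcript counts with planted differential reactions."""

    counts: dict[str, pd.Series]  # structure -> gene counts
    planted: list[str]
    planted_genes: set[str]
    fold: float
    seed: int


def generate_structure_transcripts(
    dataset: ToyDataset,
    seed: int = 0,
    planted: Sequence[str] | None = None,
    fold: float = 10.0,
    sigma: float = 0.1,
    low_count: float = 20.0,
    count_range: tuple[float, float] = (600.0, 1400.0),
    structures: Sequence[str] = ("ERM", "IRM", "ARB"),
    independent_noise: bool = False,
) -> StructureTranscripts:
    """Emit three-structure transcript profiles with planted effects.

    All genes get high baseline counts except the genes of the planted
    reactions, whose counts are low (so their transcript-derived bounds
    are the limiting ones).  Multiplicative lognormal noise (``sigma``) is
    applied to the shared baseline, and the ``IRM``/``ARB`` profiles then
    multiply the planted genes' counts by ``fold`` — the planted effect is
    the *only* true between-structure difference, so unperturbed reactions
    form an exact null.  ``fold=1`` yields a fully null experiment.  With
    ``independent_noise=True`` each structure instead receives its own
    noise draw (a stress test in which every transcript bound genuinely
    differs between structures).
    """
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    planted = list(planted) if planted is not None else list(dataset.ground_truth.planted_differential)
    unknown = [r for r in planted if r not in dataset.model.reactions]
    if unknown:
        raise ValueError(f"planted reactions not in model: {unknown}")
    planted_genes: set[str] = set()
    for rid in planted:
        planted_genes |= {g.id for g in dataset.model.reactions.get_by_id(rid).genes}
    rng = np.random.default_rng(seed)
    genes = sorted(g.id for g in dataset.model.genes)
    baseline = pd.Series(
        {g: (low_count if g in planted_genes else float(rng.uniform(*count_range))) for g in genes}
    )
    baseline = baseline * rng.lognormal(mean=0.0, sigma=sigma, size=len(baseline))
    counts: dict[str, pd.Series] = {}
    for structure in structures:
        values = baseline.copy()
        if independent_noise:
            values = values * rng.lognormal(mean=0.0, sigma=sigma, size=len(values))
        if structure != structures[0]:
            values[list(planted_genes)] *= fold
        counts[structure] = values
    return StructureTranscripts(
        counts=counts,
        planted=planted,
        planted_genes=planted_genes,
        fold=fold,
        seed=seed,
    )


def structure_medium(dataset: ToyDataset, palmitate_cap: float = STRUCTURE_PALMITATE_CAP) -> dict:
    """Medium for the structure experiment: all carbon sources at 1 M.

    Monosaccharide uptake bounds follow the transporter kinetics at the
    maximum concentration; palmitate is capped so growth is limited by the
    host-supplied lipid.
    """
    medium = {"nh4_e": 100.0, dataset.palmitate_key: palmitate_cap, "xyl_e": 10.0}
    for source, kinetics in dataset.carbon_kinetics.items():
        medium[source] = uptake_bound(kinetics, 1000.0)
    return medium


def structure_model_and_kcats(
    dataset: ToyDataset, palmitate_cap: float = STRUCTURE_PALMITATE_CAP
):
    """Split model with the structure medium applied, plus assigned kcats."""
    with_medium = apply_medium(dataset.model, structure_medium(dataset, palmitate_cap))
    split = split_reversible(with_medium)
    assignment = assign_kcats(split.model, dataset.kcat_table)
    return split.model, assignment


# ---------------------------------------------------------------------------
# Random micro-models (enumeration-oracle fodder)
# ---------------------------------------------------------------------------


def generate_random_micro_model(seed: int) -> tuple[cobra.Model, EnzymeConstraintSet]:
    """Random tiny irreversible model with <= 8 genes for oracle tests.

    A linear chain with an optional parallel branch; GPR patterns drawn
    from {none, single gene, 2-gene complex, 2-gene isozymes} with genes
    shared across reactions (promiscuity arises naturally).  The crowding
    budget is drawn small enough that enzyme constraints typically bind.
    """
    rng = np.random.default_rng(seed)
    n_genes = int(rng.integers(2, 9))
    genes = [f"g{i}" for i in range(n_genes)]
    chain_len = int(rng.integers(2, 5))
    model = cobra.Model(f"micro_{seed}")
    for j in range(chain_len + 1):
        _met(model, f"m{j}_c", f"metabolite {j}", "c")
    _rxn(model, "EX_m0", {"m0_c": -1}, bounds=(-10.0, 1000.0))
    kcat: dict[str, float] = {}

    def random_gpr() -> str:
        kind = rng.choice(["none", "single", "and", "or"], p=[0.15, 0.45, 0.2, 0.2])
        if kind == "none":
            return ""
        if kind == "single":
            return genes[int(rng.integers(n_genes))]
        pair = rng.choice(n_genes, size=2, replace=False)
        op = " and " if kind == "and" else " or "
        return op.join(genes[int(i)] for i in pair)

    step_ids = []
    for j in range(chain_len):
        rid = f"STEP{j}"
        rxn = _rxn(model, rid, {f"m{j}_c": -1, f"m{j + 1}_c": 1}, gpr=random_gpr())
        step_ids.append(rid)
        if rxn.gene_reaction_rule:
            kcat[rid] = float(rng.uniform(0.5, 20.0)) * 3600.0
    if rng.random() < 0.5:
        j = int(rng.integers(chain_len))
        rid = f"STEP{j}B"
        rxn = _rxn(model, rid, {f"m{j}_c": -1, f"m{j + 1}_c": 1}, gpr=random_gpr())
        if rxn.gene_reaction_rule:
            kcat[rid] = float(rng.uniform(0.5, 20.0)) * 3600.0
    _rxn(model, "BIO", {f"m{chain_len}_c": -1})
    model.objective = "BIO"
    mw = {g: float(rng.uniform(50.0, 300.0)) for g in genes}
    C = float(rng.uniform(0.001, 0.05))
    return model, EnzymeConstraintSet(kcat=kcat, mw=mw, C=C)


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_toy_dataset(dataset: ToyDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the dialects the pipeline consumes.

    Emits SBML (L3/fbc with groups), the medium/kcat/MW/biomass-weight
    TSVs, and a ground-truth JSON; returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["sbml"] = outdir / "toy_model.xml"
    write_sbml(dataset.model, paths["sbml"])
    paths["medium"] = outdir / "medium.tsv"
    pd.DataFrame(
        {"metabolite_id": list(dataset.default_medium), "max_uptake": list(dataset.default_medium.values())}
    ).to_csv(paths["medium"], sep="\t", index=False)
    paths["kcat"] = outdir / "kcat_table.tsv"
    dataset.kcat_table.to_csv(paths["kcat"], sep="\t", index=False)
    paths["mw"] = outdir / "molecular_weights.tsv"
    pd.DataFrame({"gene_id": list(dataset.mw), "mw_g_per_mmol": list(dataset.mw.values())}).to_csv(
        paths["mw"], sep="\t", index=False
    )
    paths["subsystems"] = outdir / "subsystems.tsv"
    pd.DataFrame(
        {"reaction_id": list(dataset.subsystems), "subsystem": list(dataset.subsystems.values())}
    ).to_csv(paths["subsystems"], sep="\t", index=False)
    paths["ground_truth"] = outdir / "ground_truth.json"
    gt = dataset.ground_truth
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "fba_optimum": gt.fba_optimum,
                "min_palmitate_uptake": gt.min_palmitate_uptake,
                "planted_differential": gt.planted_differential,
                "expected_kcats": {k: list(v) for k, v in gt.expected_kcats.items()},
                "condition_growth": gt.condition_growth,
            },
            indent=2,
        )
    )
    return paths
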