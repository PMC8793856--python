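# Methods

## Scope and model class

`ecgem` implements an enzyme-constrained extension of flux balance
analysis (FBA) for genome-scale metabolic models (GEMs), aimed at
organisms — here shaped after an arbuscular mycorrhizal fungus (AMF) —
whose growth phenotypes depend on how a limited protein budget is
allocated across enzymes.  The pipeline has five stages: model handling,
classical constraint-based analyses, turnover-number (kcat) assignment,
the eMOMENT mixed-integer program, and transcript-bounded comparison of
fungal structures.  A synthetic-data module generates toy GEMs and data
sets with planted ground truth so each stage is testable end to end.

## Constraint-based core

FBA maximizes the biomass flux v_bio subject to steady state S·v = 0 and
flux bounds; parsimonious FBA additionally minimizes the total absolute
flux at the optimum (lexicographic two-step LP); flux variability analysis
(FVA) reports per-reaction ranges at v_bio ≥ f·v_bio^opt.  These are
delegated to cobrapy (optlang/GLPK), and every returned solution is
re-audited for ‖S·v‖∞ ≤ 1e-6 and bound feasibility.  Derived analyses:

- **Blocked reactions**: FVA at fraction 0 with range within 1e-9 of {0}.
  The 1e-9 zero-tolerance is our choice; GLPK's simplex returns exact
  zeros on the toy scale.
- **Stoichiometrically balanced cycles**: reactions with nonzero FVA
  range when all boundary reactions are closed (report-only, run on the
  unsplit model — splitting would flag every reversible pair as a trivial
  two-cycle).
- **Coupling classes**: per-reaction FVA-range width compared with the
  biomass range width at tolerance 1e-3 against a default bound magnitude
  of 2000 mmol gDW⁻¹ h⁻¹; decision order (uncoupled → hard → soft →
  partial, with a non-carrying class) guarantees a partition.
- **Subsystem flux sums** are computed on the split-irreversible model so
  the sum of fluxes is linear; ATP scans maximize a sink flux at a growth
  floor, with yields per mmol of carbon uptake (not C-mol).

## Turnover-number assignment

Records (EC, substrate, lineage, value in s⁻¹) are matched per reaction:
candidates matching any full EC; filtered to substrate matches, then to
fungal-lineage records, each filter applied only when it leaves
candidates (substrate before lineage — the order is a design choice the
data sources do not fix); on no full match, the EC is pruned one level at
a time down to the class level; the **maximum** surviving value is
assigned.  GPR-bearing reactions without any match receive the **median**
of the matched values.  Values are multiplied by 3600 to h⁻¹.  Substrate
matching is case-insensitive exact name equality.  Turnover numbers are
direction-agnostic: the reverse copy of a split reaction inherits the
forward value and does not double-count in the median.

## The eMOMENT MILP

On a split-irreversible model, growth is maximized subject to

- S·v = 0 and 0 ≤ v_i ≤ E_i^r·kcat_i for every enzyme-catalyzed reaction;
- GPR recursion: complexes (AND) are limited by each operand
  (E^r ≤ each member's allocation, 1:1 subunit stoichiometry), isozymes
  (OR) add up; evaluated recursively through auxiliary variables;
- promiscuity: each gene's per-reaction allocations sum to its total
  abundance E_k^g, so a promiscuous enzyme cannot be double-counted;
- molecular crowding: Σ_k E_k^g·MW_k ≤ C (total protein, g gDW⁻¹);
- binary expression indicators with α·y_k ≤ E_k^g ≤ β·y_k,
  α = 1e-10 mmol gDW⁻¹, β = 1 mmol gDW⁻¹.

The MILP is assembled sparsely and solved with HiGHS
(`scipy.optimize.milp`) at a relative gap of 1e-9 and primal/dual/MIP
feasibility tolerances of 1e-9 — the tight MIP feasibility tolerance
matters because capacity rows carry kcat-sized coefficients (~1e5 h⁻¹),
which amplify bound slop into visible flux headroom.  Solutions are
verified post hoc (capacity, crowding, indicator bounds within 1e-6).
The whole measured protein content is available to modeled enzymes; no
unmodeled-proteome discount is applied.

**Abundance variability** minimizes/maximizes each E_k^g at
v_bio ≥ f·v_bio^opt (default f = 0.99).  **Abundance sampling** draws a
reference vector uniformly within those per-gene ranges and finds the
closest feasible abundance vector.  The distance is L1, which keeps every
step a linear MILP; an L2 variant would require a QP solver that accepts
binaries, which is not available in this stack, so the `norm` switch
accepts only `"l1"`.  Each sample retains its full supporting solution so
feasibility can be audited as raw constraint residuals rather than by
re-optimization (re-optimizing with abundances pinned is a strictly
harder test than "the sample satisfies all constraints", again because of
kcat amplification).

## Condition-specific simulation

A growth condition is one carbon source at a concentration [S] with a
measured protein content C.  The carbon uptake bound follows
Michaelis–Menten transporter kinetics, v = Vmax·[S]/(Km+[S]).  Palmitate
stays in the medium (the toy organism, like its real counterpart, cannot
grow without the host-supplied lipid) but is capped at the minimal uptake
at FBA-optimal growth so β-oxidation cannot compensate for carbohydrate
limitation.  Biomass coefficients are rescaled so the protein component's
mass fraction equals C and the remaining weighted components share 1−C,
keeping Σ coefficient·MW = 1 g gDW⁻¹; the crowding budget is set to the
same C.  Plain-FBA growth under identical bounds is reported for
contrast.

The **pool-split experiment** replaces the single crowding constraint by
two: a peroxisomal pool (α_pool·C over the β-oxidation genes) and the
remainder ((1−α_pool)·C).  Z(α_pool) is growth with myristate uptake open
divided by growth with it closed; Z > 1 marks regimes where stranded
peroxisomal budget turns myristate into a growth benefit.

**Plasticity** is the coefficient of variation (sample standard
deviation, ddof = 1, over the mean) of per-condition mean abundances or
fluxes across conditions; zero-mean entities are reported as NaN.

## Transcript-bounded structures

For each fungal structure (ERM/IRM/ARB), transcript counts are
normalized to sum 1 and converted to protein equivalents
tc^p = tc^g′·C/MW with C fixed to the maximum measured protein content
(default 0.106 g gDW⁻¹).  Reaction-level values apply the GPR rules with
AND → min and OR → max, and bound fluxes by kcat·tc^r.  Growth is FBA
under these limits (with C±σ variants for error bars); FVA at 99% of the
structure optimum defines the box for flux sampling (L1 projection of
uniform draws, as above, one LP per sample via HiGHS).  Differential
reactions between two structures are called from the nonparametric
common-language effect size A_w = (#(p>q) + 0.5·#(p=q))/(n1·n2), computed
through the rank-sum identity and verified against exhaustive pair
counting; calls use the direction-agnostic max(A_w, 1−A_w) against
thresholds 0.6/0.7/0.8.

## Synthetic data and what it does (not) show

The default toy GEM has ~33 reactions, 19 genes and three compartments
(cytosol, peroxisome, extracellular), with every GPR pattern (a complex,
an isozyme pair, a promiscuous gene), an obligatory palmitate uptake, a
peroxisomal myristate β-oxidation branch, and a mass-normalized biomass
(protein 0.40 / lipid 0.35 / carbohydrate 0.25 by default).  Ground
truths (FBA optimum, minimal palmitate uptake) are recomputed at
generation time by an independent HiGHS LP, separate from the
cobrapy/GLPK analysis path.  The kcat table plants one case per matching
rule; the planted median works out to 24 s⁻¹.

The 12-condition design (4 sources × 10/100/1000 mM) uses protein
contents of 0.016–0.037 g gDW⁻¹, chosen so the crowding budget is the
limiting resource in most conditions — the regime enzyme-constrained
models exist for; the planted "dry weight" is a strictly monotone
transform of the pipeline's own growth prediction, so rank recovery
(Spearman ρ = 1) checks pipeline self-consistency and determinism, not
predictive power on real data.

The structure experiment feeds all four sugars at 1 M and caps palmitate
low (0.08 mmol gDW⁻¹ h⁻¹) so growth is lipid-limited and every
unperturbed transcript bound keeps slack; the planted differential
reaction sits on a dedicated xylose→xylitol side chain whose only
enzymatic step carries low baseline counts, multiplied by `fold` in
IRM/ARB.  Lognormal noise (σ = 0.1) is applied to the **shared** baseline
rather than per structure, so the planted fold is the only true
between-structure difference and unperturbed reactions form an exact
null; an `independent_noise` switch exists for stress tests, under which
spurious A_w > 0.6 calls are expected because every bound then genuinely
differs between structures.  Real transcriptome replicates carry
between-condition noise, unknown fold patterns and transcript–protein
decoupling that this generator does not emulate; passing tests
demonstrate correctness of the machinery, not biological validity.

## Numerical choices and limitations

- Solvers: GLPK (via cobrapy/optlang) for LP analyses; HiGHS (via scipy)
  for the MILP, sampling projections and generation-time oracles.  The
  two independent solver paths cross-check each other in the tests.
- Problem sizes are desk-scale: sampling audits run at 100 samples and
  the recovery experiment at 500 samples per structure (the package's
  defaults remain 1000/5000).
- Uptake sign convention: negative exchange flux externally; positive
  reverse-copy flux after splitting.
- Degenerate inputs: empty media close all uptake; zero protein budget
  gives zero growth; genes forced unexpressed zero out their reactions;
  zero total transcript counts and non-positive kcat values are errors.
- The MILP's indicator constraints make the feasible set non-convex;
  sampled abundance/flux sets are projections of uniform box draws, not
  uniform samples of the feasible region — matching the method it
  implements, but not an unbiased volume sampler.
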