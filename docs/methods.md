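# Methods

## Thermokinetic model

Activity–temperature data are modelled as an Arrhenius law modulated by a
two-state thermal-inactivation equilibrium:

    k(T) = exp(lnA − Ea/(R·T)) · f_active(T),
    f_active(T) = 1 / (1 + exp(−(ΔH_u/R)·(1/T − 1/T_m)))

Below the optimum, f_active ≈ 1 and ln k is linear in 1/T; above it the
folded fraction collapses. Both limbs are fitted by ordinary least squares
of ln k on 1/T. The maximal-rate point terminates the ascending limb and
starts the descending one (ties break toward lower temperature, logged);
each limb needs at least three points. Zero rates at the window edges are
trimmed before the log transform (warned); interior zeros are an error
because a log-linear fit is undefined there. The ascending slope yields
Ea = −slope·R (reported positive for sensible data); the descending slope is
reported signed, as an apparent parameter with no transition-state reading.

Transition-state decomposition uses the Eyring equation
k = κ·(k_B·T/h)·exp(−ΔG‡/RT) with κ = 1 by default (no experimental
transmission coefficient is available; κ is configurable). The
solution-phase convention ΔH‡ = Ea − RT is used, as standard for enzyme
kinetics in solution (not the gas-phase Ea − 2RT), and ΔS‡ = (ΔH‡ − ΔG‡)/T.
All temperatures are Kelvin internally; the CLI accepts °C and converts.
Rates in s⁻¹ (k_cat) and specific activities in U/mg fit identically —
Arrhenius slopes are invariant to constant scaling — so the unit is carried
as an opaque tag.

When the reference temperature lies on the measurement grid, enzyme-level
ΔG‡ uses the observed rate there rather than the fitted extrapolation:
multiplicative distortions shared by the two enzymes (e.g. partial thermal
inactivation) then cancel exactly in psychrophile-minus-mesophile
differentials. Differentials can also be recovered from rate ratios at two
temperatures via ΔΔG‡(T) = −RT·ln(k_p/k_m) and the linear identity
ΔΔG‡ = ΔΔH‡ − T·ΔΔS‡; this two-point solve is exact on noiseless data for
the same cancellation reason.

Activity profiles (pH, temperature) are summarized by the optimum and a
plateau: the maximal contiguous run around the optimum with activity
≥ 0.9·max (the fraction is configurable and logged; a plateau is only
reported when it spans at least two grid steps, so a single-point maximum
stays a peak). The calcium profile summary is purely descriptive — the
molar ratio at maximal activity and the zero-calcium activity fraction,
reported as absent rather than interpolated when no zero point was
measured.

## Surface exposure and stabilizing contacts

Solvent-accessible surface area uses the Shrake–Rupley construction with a
deterministic golden-spiral lattice (default 960 points per atom) instead of
random sampling, so results are bit-reproducible. A lattice point on the
probe-expanded sphere (probe 1.4 Å) is exposed when it lies strictly farther
than r_j + probe from every other atom center. Hydrogens are ignored
(united-atom surface; models and crystal structures typically lack them)
with Bondi-type radii C 1.70, N 1.55, O 1.52, S/P 1.80 Å, overridable.
Lattice resolution bounds per-atom reproducibility under rigid motion at a
few point-areas (~0.1 Å² per point for a carbon sphere); structure-level
totals agree to well under 0.5%.

Relative side-chain exposure divides side-chain SASA (atoms beyond the
backbone, CB included; CA stands in for glycine) by per-residue-type
reference maxima computed on extended Gly-X-Gly tripeptides with the same
algorithm, radii and probe (`scripts/generate_reference_sasa.py`
regenerates the table). Self-consistency is the point: published maxima
computed with hydrogens or other radii run ~20% high against a united-atom
surface and would distort the normalization. Values slightly above 1 occur
in unusual conformations and are capped at 1.2 (logged). Residues with no
resolved side-chain atoms report an absent exposure, never zero.

Salt bridges are recorded when any basic side-chain nitrogen (Lys NZ, Arg
NH1/NH2/NE) lies within 4.0 Å of any acidic side-chain oxygen (Asp OD1/OD2,
Glu OE1/OE2). "Near a disulfide" means within 2 residues in sequence or
5.0 Å in space of a disulfide cysteine. All three cutoffs are qualitative
conventions, configurable and embedded in report provenance. Residue
numbers are taken verbatim from the coordinate file, preserving zymogen
numbering.

## Autolysis model

Candidate self-cleavage sites are every Lys/Arg with a scissile bond
(the C-terminal residue has none); sites followed by proline are excluded
by default, reading the strongly reduced tryptic activity before proline as
negligible self-cleavage (a permissive mode keeps them flagged instead). A
site is labile when its relative side-chain exposure is ≥ 0.30 — the
default threshold follows the exposure reported for the principal krill
trypsin autolysis site — and it is neither salt-bridged nor near a
disulfide. Sites without structural coverage are kept, flagged unassessed,
rather than silently dropped.

Cleavage patterns are all subsets of the filtered sites (guarded at 12
sites; the guard must be raised explicitly). Cutting after each pattern
position yields closed intervals in zymogen numbering; intervals are merged
into fragment groups by union-find over the disulfide pairs, because
disulfide-linked fragments co-migrate as one band on a non-reducing gel.
Group mass is the sum of average residue masses plus one water per
fragment interval plus retained tag masses (N-tag travels with the first
interval, C-tag with the last); average masses are the default because
SDS-PAGE resolution justifies nothing finer, with monoisotopic behind a
flag, and the reduced convention (no −2H per disulfide) is the default with
oxidized mode opt-in. The catalytic triad is a required input annotation
(its residue numbers are not computable from sequence); a pattern disrupts
it when triad members land in two or more groups.

A band is explained by a pattern when some group mass lies within the
band's tolerance and, for His-probe-flagged bands, the group's tag
retention matches. Patterns are scored lexicographically: explained bands
(more is better), then unexplained predicted groups above a 5 kDa
reportable-mass floor (fewer is better — smaller peptides migrate out of
the gel and are not penalized), then pattern size (parsimony). Ties keep
enumeration order and are logged. The default band tolerance for real gel
data is ±1.5 kDa, deliberately wide because acidic trypsins migrate
anomalously in SDS-PAGE; simulated bands carry a 3σ tolerance instead since
their error model is known.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of (spec, seed) using numpy's `default_rng`.

The enzyme-pair generator scales mesophile rates pointwise by
exp(−(ΔΔH‡ − T·ΔΔS‡)/(RT)) before noise; the default planted differentials
(ΔΔH‡ = −57.4 kJ/mol, ΔΔS‡ = −191.2 J/mol/K) were chosen by a two-point
solve so the pair reproduces a 1.74× activity ratio at 20 °C (ΔΔG‡ =
−1.35 kJ/mol) and ~4× at 10 °C — the enthalpy–entropy compensation
signature of cold adaptation. The default mesophile (Ea = 75 kJ/mol,
k(20 °C) = 1 s⁻¹, T_m = 328 K, ΔH_u = 400 kJ/mol) keeps the derived
psychrophile's apparent activation energy positive, which any mesophile
with Ea < 57.4 kJ/mol would not. Measurement noise is multiplicative
lognormal. The two-state inactivation limb is a generator convention that
produces the observed two-limbed Arrhenius shape; it is not an inference
about the real unfolding mechanism.

Protein fixtures plant 2–5 candidate K/R sites with ≥ 50 residues between
sites and termini, so every fragment stays above the 5 kDa gel floor and
cleavage patterns remain distinguishable by mass; disulfide pairs are
placed within the segments between planted labile cuts (a bridge across a
cut would make that cut invisible on a non-reducing gel). Exposure values
and contact flags are drawn so that exactly the planted labile sites pass
the filter; non-labile sites fail by low exposure, a salt bridge or
disulfide proximity at random. The background alphabet excludes K/R/C/P to
keep the planted structure exact. Band observations are true group masses
with Gaussian error (σ = 0.2 kDa by default), sub-floor groups dropped, and
tag flags set from tag retention.

Consequently, passing the planted-recovery tests shows the pipeline is
correct and well-behaved under its own assumptions — Gaussian band error,
resolvable fragments, correct disulfide annotation. It does not show
robustness to anomalous electrophoretic migration, partial digestion
ladders, co-migrating contaminant bands, or wrong disulfide maps, none of
which the generator emulates.

The extended-peptide builder (φ = ψ = ω = 180°, ideal bond geometry, CCD
ideal-coordinate side chains grafted rigidly by superposition) exists to
give surface calculations a deterministic, self-consistent reference
conformation; it is not a conformer prediction.

## Sequence conventions

Peptide mass = Σ residue average masses + 18.01528 Da (+ tag masses);
cysteines are treated as reduced by default, consistent with the deposited
mature-chain mass convention. Net charge is the Henderson–Hasselbalch sum
over side chains and both termini; the pI is found by bisection on the
strictly pH-monotone charge to |charge| < 1e−6. The shipped default pKa set
is the Bjellqvist-style table used by common web pI calculators, with an
EMBOSS alternative; reported pI values are tagged with the table name
because acidic-protein pI estimates shift by a few tenths between tables.
Pairwise identity uses global alignment (match +1, mismatch 0, linear gap
−1, Biopython's deterministic traceback) with the alignment length as
denominator — declared because conventions differ, though for equal-length
precursors the choice is nearly moot.

Precursor parsing anchors the mature chain at the first IVGG motif and
takes the signal (default 15 residues) and activation peptide (default 14)
as annotations. When annotation lengths and motif offset disagree — as they
do for the deposited krill isoforms, where 15 + 14 + 236 = 265 ≠ 266 — the
parse succeeds with an explicit inconsistency flag and warning; the
discrepancy is surfaced, not resolved by guessing.

## Problem sizes and numerical choices

Default SASA lattice: 960 points (isolated-sphere error < 1%; doubling
changes overlapping-pair areas < 0.5%). Arrhenius recovery statistics use
n = 10 temperatures, σ = 0.05, 200 seeds; planted-pattern recovery uses 100
fixtures of length 150–300 with σ = 0.2 kDa band noise. Bisection for pI
runs to 1e−6 in charge within pH [0, 14]. Mass conservation across any
cleavage (Σ group masses = intact + cuts·water) holds to 1e−6 Da by
construction and is asserted in tests. The pattern-enumeration guard (12
sites, 4096 subsets) bounds the exhaustive search; ranking is O(patterns ×
groups × bands).

## Known limitations

- The exposure threshold (0.30) and contact cutoffs encode qualitative
  structural reasoning; they are defaults to be tuned per system, not
  measured constants.
- The descending Arrhenius limb is summarized, never mechanistically
  modelled; no Michaelis–Menten constants are estimated.
- Autolysis is treated combinatorially (which patterns explain the gel),
  not kinetically (how fast each site is cleaved); relative stabilities of
  engineered variants are therefore out of reach.
- The pI model ignores charge–charge interactions and folded-state pKa
  shifts; it is the standard sequence-only estimate.
- Structure handling is single-conformation and single-chain-set; no
  modelling, minimization or dynamics.
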