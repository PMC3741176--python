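# psychrotryp

Thermokinetic characterization and autolysis-site prediction for
cold-adapted (psychrophilic) trypsins, built around the comparative analysis
of a krill trypsin versus mesophilic pig trypsin.

Psychrophilic enzymes outperform their mesophilic homologs at low
temperature by lowering the activation enthalpy of catalysis at the cost of
a compensating activation-entropy penalty. The same structural flexibility
that buys cold activity tends to make these proteases aggressively
self-digesting, so the second half of the story is predicting *where* a
trypsin cuts itself and which cleavage pattern explains the fragment bands
seen on an SDS-PAGE gel. `psychrotryp` implements both analyses as a tested
library plus a CLI, with seeded synthetic-data generators so every stage is
testable without downloads.

## What it computes

**Transition-state thermokinetics.** For activity–temperature series the
package fits both limbs of the Arrhenius plot (ln *k* vs 1/*T*; ascending
limb gives *E*ₐ = −slope·*R*), converts rates to activation free energies
through the Eyring equation

&nbsp;&nbsp;&nbsp;&nbsp;*k* = κ·(k_B·*T*/h)·exp(−ΔG‡/RT),&nbsp;&nbsp;
ΔH‡ = *E*ₐ − RT,&nbsp;&nbsp; ΔS‡ = (ΔH‡ − ΔG‡)/*T*,

and reports psychrophile-minus-mesophile differentials Δ(ΔG‡), Δ(ΔH‡),
TΔ(ΔS‡) at a shared reference temperature. A Δ(ΔG‡) of −1.35 kJ/mol at
20 °C, for example, is equivalent to a 1.74-fold activity advantage, growing
to ~4-fold at 10 °C when ΔH‡ is lower for the cold enzyme.

**Autolysis-site prediction.** Trypsins cleave after Lys/Arg (weakly before
Pro). Candidate self-cleavage sites are filtered by structural context:
relative side-chain exposure (Shrake–Rupley SASA against extended Gly-X-Gly
reference maxima), salt bridges (basic N within 4 Å of acidic O) and nearby
disulfides. Cleavage patterns over the surviving sites are enumerated, each
pattern's fragments are merged into disulfide-linked groups (co-migrating
bands under non-reducing conditions), group masses (average masses + one
water per peptide ± tag masses) are matched against observed band masses,
and patterns are ranked by explained bands, parsimony and unexplained
predicted groups. Catalytic-triad disruption is flagged per pattern.

**Sequence utilities.** FASTA I/O, average/monoisotopic peptide mass, net
charge and isoelectric point (Henderson–Hasselbalch + bisection, Bjellqvist
or EMBOSS pKa tables), global-alignment percent identity, zymogen precursor
parsing (signal / activation peptide / IVGG-initiated mature chain), codon
arithmetic.

## Worked example

Simulate a noiseless psychrophile/mesophile pair with planted differentials
(ΔΔH‡ = −57.4 kJ/mol, ΔΔS‡ = −191.2 J/mol/K) and analyze it:

```sh
psychrotryp simulate thermo --seed 3 --sigma 0 --out act.csv
psychrotryp thermo compare --in act.csv --psychro KT --meso PT --tref-c 20 --out rep.json
```

The report contains, per series, the fitted limbs and Eyring state, e.g.
(kJ/mol): `KT` ΔG‡ = 70.41, `PT` ΔG‡ = 71.76, optima near 50 °C — and the
differential block:

```
"ddG_kJ_mol": -1.3497,
"ddH_kJ_mol": -56.3485,
"TddS_kJ_mol": -54.9988,
"activity_ratio_at_T_ref": 1.7398
```

i.e. the planted Δ(ΔG‡) is recovered exactly at the 20 °C reference and is
read as "the cold enzyme is 74% more active". The autolysis side:

```sh
psychrotryp simulate protein --seed 8 --sites 3 --labile 1 --out-fasta p.fa --out-annot p.json
psychrotryp simulate bands   --seed 8 --sites 3 --labile 1 --out bands.csv
psychrotryp autolysis predict --fasta p.fa --annot p.json --bands bands.csv \
    --exposure exposure.csv --text --out rank.json
```

prints the candidate table and ranking:

```
site K73:  exposure=0.43, salt_bridged=False, near_disulfide=True  -> labile=False
site R133: exposure=0.20, salt_bridged=False, near_disulfide=False -> labile=False
site R222: exposure=0.60, salt_bridged=False, near_disulfide=False -> labile=True
top pattern: cut after [222]; explains 2 band(s); triad disrupted: False
```

— the one exposed, unstabilized site is the planted cut, and its two
fragment-group masses explain both observed bands.

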