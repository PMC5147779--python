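# Methods

## Scope and model anatomy

`yeastcycle` models the core CDK control network of the budding-yeast cell
cycle as a closed mass-action reaction system and simulates it either
exactly (Gillespie SSA in a growing cell) or deterministically (ODEs with
symmetric division).  The network covers Start (Cln3 → Whi5 ∤ SBF →
Cln1,2/Clb5), S/M entry (Fkh2 → Clb2 with Clb2-mediated positive
feedback), and mitotic exit (Clb2 → APC phosphorylation → Cdc20:APC →
cyclin/Ht1 destruction → Net1 phosphorylation → Cdc14 release → Sic1,
Cdh1, Swi5 reactivation).  Checkpoint machinery (the mitotic checkpoint
complex, securin/separase, the FEAR and MEN pathways) is deliberately
outside scope: the network proceeds "automatically" from metaphase to
exit.  "Sic1" is a composite of Sic1 plus the inhibitory domain of Cdc6;
"Clb5" stands for Clb5 + Clb6 and "Clb2" for Clb1 + Clb2; Cdc28 is not a
species — every cyclin count is read as the corresponding cyclin:CDK
activity.  Two phosphatases close the loops: Ht1, an unspecified
Net1-directed phosphatase destroyed by Cdc20:APC, and Hbf, a constitutive
generic phosphatase opposing CDK everywhere else.

## Rates and volume scaling

All reactions are elementary (at most two reactants) with concentration-
based rate constants (nM, min).  In a cell of volume V fL the propensity
rules are: zero-order synthesis k·Ω(V) with Ω = V/1.67 molecules/nM;
unimolecular k·N; bimolecular k·N₁N₂/Ω (k·N(N−1)/2Ω for homodimers);
transcription per gene copy k·N_promoter with **no** volume factor, so
constitutive mRNA *numbers* are stationary over the cycle; and translation
k·N_mRNA·(V/V_ref)^e with e = 1 — translation tracks ribosome content, so
protein numbers track volume and concentrations are homeostatic — except
*CLN3* with e = 2, which makes the Cln3 *concentration* grow ∝ V and
implements size sensing.  V_ref = 50 fL is the volume at which the
concentration-based rates were calibrated.

Gene activity in the stochastic engine is a discrete two-state promoter
(haploid copy number 1) with TF-dependent activation (bimolecular in the
active TF form) and constant deactivation; the continuous gene-activity
variable of the deterministic formulation is recovered as the occupancy
probability r_on/(r_on + k_off).

## Multisite phosphorylation

Eight proteins carry distributive phosphorylation chains with site counts
and activity rules: Whi5 (n = 10, active/nuclear with k ≤ 2), SBF (4, 0),
Sic1 (9, 5), Cdh1 (11, 0), Net1 (8, 3), Swi5 (3, 0), Fkh2 (2, active only
fully phosphorylated) and APC (11, graded).  All chains are ordered except
Sic1, which phosphorylates in random (disordered) site order; with
site-symmetric rates the 2⁹ site-resolved states reduce exactly to 10
count-resolved states carrying combinatorial multiplicities (n−k on
phosphorylation out of state k, k on dephosphorylation) — validated
against a brute-force site-resolved master equation at n ≤ 3.  APC
phospho-form k binds Cdc20 at a rate scaled by β^(n−k) with β = 0.525;
every Cdc20:APC form is equally potent, so ligase activity emerges with a
delay set by the phosphorylation ladder, which is what postpones cyclin
destruction until mitosis is fully engaged.

Complexes (Whi5:SBF for Whi5 forms with k ≤ 2; Sic1:Clb5 and Sic1:Clb2
for Sic1 forms with k ≤ 5; Net1:Cdc14 for Net1 forms with k ≤ 3) remain
kinase substrates; the phosphorylation that takes the inhibitor past its
activity limit ejects the partner.  Complexed proteins are shielded from
basal turnover — a simplification that slightly enriches sequestered pools.

## Calibration

The package does not ship a transcribed supplement-scale rate table; the
defaults in `params.py` were produced by the package's own calibration
helper against published population anchors:

* mRNA means 5–10 copies/cell, half-lives 5–10 min, except 3 min for the
  G1/S cyclin mRNAs (*CLN1*, *CLN2*, *CLB5*);
* protein abundances of 500–9000 copies (25–300 nM at V_ref), with
  half-lives of 6–60 min by stability class;
* growth media: glucose μ = 0.007 min⁻¹ (MDT 99 min) with daughter volume
  fraction f = 0.40; galactose 0.00467 (148) / 0.36;
  glycerol-ethanol 0.00398 (174) / 0.35.

For a constitutive gene the helper inverts the birth–death balance,
including growth dilution: on the balanced-growth path protein numbers
track volume, so the stationary concentration is
1.67·k_tl·M/(V_ref·(δ_p + μ)) and k_tl carries the (δ_p + μ) factor
(calibrated at the glucose μ; concentrations shift modestly across media,
as protein histograms do in slower media).  Two rates depart from the
plain inversion: Clb2 translation is raised so the mitotic peak
(~250–300 nM) can build within ~25 min, and Cdc20 translation is lowered
so the Cdc20:APC ligase assembles with a delay after Clb2 rises.  Clb2
synthesis additionally carries a medium-indexed transcription multiplier
(1.00 / 0.80 / 0.72 for glucose / galactose / glycerol-ethanol): mitotic
cyclin accumulation tracks the specific growth rate, which is what lets
slow media rescue strains burdened by excess Clb2.  Kinase/phosphatase
constants were then tuned against the deterministic engine until the
wild-type glucose limit cycle divides with the 99-min mass doubling time
and a realistic phase anatomy, and against small stochastic cultures for
the Start statistics.  The full audit trail is exportable
(`yeastcycle export-network`).

## Events and thresholds

Budding and DNA-synthesis onset are scored by continuous indicator
variables, not molecules: dx/dt = k_s·c − k_d·x with k_s = k_d =
0.2 min⁻¹, where c is an efficiency-weighted sum of free cyclin
concentrations (budding: Cln1, Cln2 0.4, Cln3 0.1, Clb5 0.2, Clb2 0.05 —
all G1/S cyclins contribute; DNA: Clb5 0.8, Clb2 0.3 — B-type cyclins
only).  Thresholds: bud_ss 25 nM, dna_ss 30 nM.  Division fires on a
downward crossing of free [Clb2] through 12.5 nM, armed only after [Clb2]
has exceeded 25 nM (2× the threshold — an invented, configurable guard
that stops newborn G1 cells from re-triggering).  Whi5 is nuclear while
the summed concentration of Whi5 species with ≤ 2 phosphates (free or
SBF-bound) exceeds 200 nM.  Gene-activation ages for *CLN2*, *RAD27* and
*CLB2* are the first upward crossings of the occupancy-probability
activity (thresholds 0.15 / 0.2 / 0.2) smoothed by a 1-min moving
average.  A binary single-copy promoter trace was tried first and
rejected: a single stochastic binding episode (mean lifetime 1/k_off)
saturates any short moving average, producing spurious "activations" at
baseline; the occupancy probability is the signal the thresholds
presuppose.  Cells that miss budding, DNA onset or division for the
arrest window (500 min default) are classified unbudded / unreplicated /
M-phase arrested; the labels partition non-dividers.

*RAD27* represents the G1/S regulon readout: a promoter activated by
Cln1, Cln2, Cln3 and Clb5 with distinct efficiencies, carrying no mRNA or
protein species.

## Stochastic engine

Direct-method SSA over the compiled reaction arrays.  Volume grows
exponentially but is held constant between forced clock boundaries every
Δ = 0.1 min (μΔ ≲ 7×10⁻⁴, <0.1% volume error per interval), at which
propensities are refreshed in full, indicators advanced exactly, and
events scored; between boundaries propensities are maintained
incrementally through a species→reaction dependency graph with 32-wide
partial sums for selection.  A wild-type glucose cycle fires ~3–4 million
reaction events.  Per-cell randomness comes from a counter-based stream
derived from (master seed, cell id), so cultures are bit-reproducible
regardless of scheduling; identical inputs give identical outputs.

At division the daughter receives volume f·V and, per species,
round-half-up(f·N) in the default proportional mode or a Binomial(N, f)
draw in the extrinsic-noise mode; the mother keeps the remainder, so
totals are conserved exactly.  Cln3 partitions 25:75
daughter:mother — newborn daughters carry ~3-fold less Cln3, the
daughter-specific Start delay.  Gene copies duplicate into both progeny;
indicators reset to zero in both.  Optional Gaussian noise on f (given
CV) is truncated to (0.05, 0.95) by resampling.

## Deterministic engine

The ODE right-hand side is exactly the stoichiometry-weighted propensity
vector evaluated at real-valued states — one rate table for both engines,
enforced by a consistency test at 1e-9.  States are integrated in
molecule-number units (growth enters through the volume-scaled rates; no
explicit −μC dilution term), with LSODA and event location on integrator
dense output.  Division is symmetric: all molecular species halve, gene
copies do not, indicators reset.  The wild-type glucose run converges to
a limit cycle whose period equals the mass doubling time (balanced
growth); in the two slow media the symmetric-division return map
period-doubles (alternating short/long cycles averaging the MDT) — an
inherited-state effect of the deterministic map that the stochastic,
asymmetric engine does not show.

## Statistics

Implemented exactly as used on the simulated populations: CV with the
n−1 denominator; product-moment correlation; number doubling time as
ln2/slope of a least-squares fit to ln(count) vs time after discarding a
transient; the size-control regression of y = μ·T_unbud on
x = ln(V_bir/⟨V_bud⟩) through equal-count-binned means (slope −1 = strict
sizer, 0 = timer; invariant to common volume rescaling); Poisson MLE and
a two-component Poisson mixture by EM (multiple restarts, 1e-8
log-likelihood tolerance, AIC for model choice); and per-cell Sic1 decay
by exponential regression over the Start collapse — from the last point
above 80% of the pre-trough peak down to max(5 molecules, 1% of peak),
since total Sic1 plateaus through G1 before collapsing and is
re-synthesised in telophase; fitting from the raw maximum would measure
G1 length, not turnover.

## Synthetic-data scope: what the generator does and does not emulate

The computational culture generates the study conditions itself: founder
cells start from a G1-like state at 30 fL and all statistics are taken
after discarding the founder transient.  The generator reproduces
asymmetric division, size control, pedigree structure and molecular noise
from discrete chemistry; it does not model nutrient depletion, cell
death, spatial structure, checkpoint arrest, or measurement noise
(microscopy segmentation, FISH spot calling).  Passing tests therefore
validate the control network's noise propagation under the model's
assumptions — they do not certify agreement with any particular
wet-lab measurement pipeline.

## Problem sizes

Full-population studies in this domain use hundreds to thousands of
single-cycle cells; the shipped test and acceptance runs use cultures of
16–40 cells per condition and a 350–500-min arrest window, sizes chosen
so that each qualitative ordering (feedback strength vs. activation
coherence, size control across media, Sic1 turnover across S-cyclin
deletions, the budded-phase structure of cycle variability) is resolved
while a complete run stays at minutes of CPU.  Means are stable at these
sizes; second-moment statistics (CVs, correlations of CVs) carry visible
sampling error, which the ordering-style assertions tolerate by
construction.

## Known limitations

* The rate table is this package's own calibration, not a transcription
  of any published parameter set; absolute mutant phenotypes (arrest
  percentages, mutant NDTs) are indicative, not quantitative.
* cdh1 deletion is partially viable with long cycles, but the arrested
  fraction is seed- and window-sensitive at small culture sizes.
* In cln1 cln2 deletions the population re-equilibrates at larger birth
  sizes, so SBF-release ages shorten even though every downstream event
  (budding, DNA onset, division) is delayed; activation-age variance
  comparisons across strains should therefore use the feedback-strength
  scan (scaling the Whi5-phosphorylation constants in an otherwise
  wild-type cell), which is also the cleaner in-silico experiment.
* Complexed proteins escape basal turnover; sequestered totals
  (e.g. RENT) run ~20–30% above the naive design targets.
* The deterministic engine's period-doubling in slow media (above) is a
  property of the symmetric-division map, left as-is.
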