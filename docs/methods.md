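# Methods

## Setting

A microbial electrolysis cell (MEC) ferments xylose (the dominant pentose of
lignocellulosic hydrolysates) with a mixed activated-sludge inoculum while the
working electrode is held at a fixed potential vs SHE. Over a 150-h batch the
measurable outputs are endpoint concentrations of ethanol and acetate, the
amount of H₂ in the headspace, optionally a biomass estimate, and the
chronoamperometric current trace. `fermbal` closes the electron and carbon
books over those measurements and, in a second stage, quantifies how the
applied potential reshapes the 16S community.

## Balance model

Let ΔC be the consumed substrate (g L⁻¹), M = 150.13 g mol⁻¹ the xylose molar
mass, V the liquid volume (L), F = 96 485 C mol⁻¹ e⁻.

* **Degradation rate** = ΔC / C₀ (reported as %).
* **Metabolite coulombs** C = F · b · V · Δn, with Δn the molar concentration
  change. `b` is the *net* electron count per mole of product formed from
  0.6 mol xylose: ethanol 3.4, acetate 0.6, H₂ 2 (xylose itself 20). The API
  takes Δn in µmol L⁻¹ directly and never divides by a product molar mass:
  that is the only reading of the equation consistent with the per-product
  coulombs the balance is meant to produce.
* **Charge from current** C_I = ∫ I dt, trapezoidal on the hour-stamped
  samples converted to seconds, no resampling; the sign of the current is
  kept, so a net-consuming reactor has C_I < 0.
* **Coulombic efficiency** CE = |C_I| / (F · 20 · V·ΔC/M) · 100 %. The
  magnitude is used so a negative-charge reactor still reports a positive CE.
* **Cathodic gas recovery** r_CAT = C_H2 / |C_I| · 100 %, with
  C_H2 = 2 F n_H2.
* **CCE / ECE shares.** Per pool, the share of consumed-substrate carbon is
  c_pool·n_pool / (5·n_consumed) and of electron equivalents
  e_pool·n_pool / (20·n_consumed), with full-oxidation equivalents
  (ethanol 12, acetate 8, H₂ 2, biomass C₅H₇O₂N 20). H₂ enters only the
  electron books (it has no carbon); its absolute moles are compared against
  consumed moles = concentration × volume. Because the equivalents are fixed,
  ECE_ethanol = 1.5 × CCE_ethanol and ECE_acetate = CCE_acetate identically —
  useful internal consistency checks. `unaccounted = 100 − Σ shares` may go
  negative only with the `overaccounted` flag raised (and a warning), since it
  signals inconsistent inputs rather than a physical pool.
* Secondary oxidation of ethanol/acetate and any kinetic modelling are out of
  scope; the balance is endpoint arithmetic.

The no-potential control carries `applied_potential = None` and no trace; CE
and r_CAT are reported as not-applicable (`None`) rather than zero.

## Trace summaries

Chronoamperometry peaks are the global maximum of the trace (earliest sample
on ties). Acclimation voltage traces are segmented into feed cycles at the
0.001 V refeed threshold: a cycle opens at the first sample above threshold
and a new one at each upward crossing after at least one sample below it (a
one-sample dwell as hysteresis against noise splits). No smoothing is applied
before peak detection.

## Community statistics

Counts tables are samples × OTUs. Rarefaction subsamples without replacement
(multivariate hypergeometric), dropping under-depth samples with a warning;
the default depth is the minimum sample sum. Alpha diversity: Shannon
(default log base 2 — the base is explicit everywhere because conventions
vary), observed species, Chao1 in the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)) (classic form by flag), and Faith's PD as the sum
of branch lengths connecting the present taxa to the root. PD includes the
root path by default ("whole tree" convention) and is computed in-package by
union of root paths so multifurcating (e.g. star) trees work; scikit-bio's
implementation is the cross-check in the tests.

Beta diversity uses Bray–Curtis on raw counts. NMDS is SMACOF majorization
with isotonic (pool-adjacent-violators) disparities: defaults k = 2,
20 random restarts, tolerance 10⁻⁶ on Kruskal stress-1, 300 iterations max;
the per-iteration stress trace is recorded (it must be non-increasing) and
the whole procedure is bit-reproducible under its seed. PERMANOVA is
Anderson's pseudo-F with label permutations (default 9 999), reporting
R² = SS_between/SS_total and p = (#{F* ≥ F} + 1)/(n_perm + 1); it is
implemented in-package because the result contract needs R² and a seeded
permutation stream, with scikit-bio's permanova as the oracle in tests.

Family-level profiles pool unclassified taxa as "Other" and normalize per
sample. Group differences are Welch two-sample t-tests per family with a 95 %
CI on the mean difference; Welch is used because group sizes are small and
variances visibly unequal across treatments. P-values are reported raw — the
downstream presentation decides on multiplicity handling.

## Synthetic data

The generator emulates the *structure* of the study's measurements, not its
sequences:

* **Reactor batches.** Panels are exactly consistent with the configured
  consumption fraction and molar yields. The current trace is a log-normal
  shaped single pulse — the peak height and time are meaningful, the shape is
  a modelling convenience — whose width is solved (Brent) so the trapezoidal
  charge matches the target C_I within 1 %; optional additive Gaussian noise.
  Biomass is back-computed to close the carbon balance to a configured
  unaccounted fraction (default 0.4 of consumed carbon left to CO₂ and
  unmeasured products), since no biomass assay is modelled. Infeasible
  targets (product carbon exceeding the accounted fraction, charge outside
  what the pulse can carry) raise with the violated bound.
* **Endpoint fixture.** The five published reactor batches (control,
  −0.058 V, +0.242 V, +0.542 V, +0.842 V at 4 g L⁻¹ xylose, 0.1 L, 150 h)
  are carried verbatim: endpoint concentrations, H₂ amounts and integrated
  charges as printed. Two printed inconsistencies are carried as-is rather
  than reconciled: the +0.242 V H₂ amount (0.12 µmol) does not match its
  printed charge (0.118 C), and the +0.542 V consumption is quoted both as
  95.5 % and 92.4 % (the fixture uses 95.5 %, which is consistent with the
  printed 0.030 mol mol⁻¹ yield).
* **Communities.** Pre-treatment samples are Dirichlet-multinomial around a
  diffuse 50-taxon / 12-family baseline (precision 200, depth 10 000 reads);
  post-treatment samples concentrate two families to a configured combined
  abundance, default 0.95 — inside the 54–99.7 % dominance range such
  treatments produce. Trees are random coalescents with exponential
  intervals. All randomness flows through one seeded generator; identical
  seeds give identical outputs.

What passing tests show: the analysis recovers exactly the structure the
generator encodes (yields, charges, dominance shifts, group separation).
What they do not show: behaviour on real amplicon data with chimeras,
compositional artefacts, overdispersion beyond Dirichlet-multinomial, or
real electrode noise — none of which the generator emulates.

## Numerical choices and problem sizes

Charge integration and pulse solving work on fine grids (2 001-point traces;
20 001-point grid inside the width solver). NMDS ties are irrelevant to the
isotonic fit because ranks are taken with a stable sort. PERMANOVA p-values
are permutation-resolution limited: with triplicate groups the attainable
floor is ≈ 0.1, which is why the study-scale driver reports R² alongside p.
Test-suite simulations are desk-scale by design (≤ 26 samples, ≤ 50 taxa,
200 null replicates at 99 permutations); they complete in seconds while
leaving the estimators in their asymptotically valid regimes.

## Known limitations

* The printed coulombic efficiencies of the source batches cannot be
  reproduced from the printed consumptions and charges by the CE equation;
  the package follows the equation, so its CE values differ from those four
  printed numbers (the inputs actually used for them are unstated).
* Biomass electron/carbon equivalence (C₅H₇O₂N, ratio 1) is assumed; where a
  source reports unequal biomass carbon and electron shares the package
  cannot represent that asymmetry.
* NMDS stress monotonicity is guaranteed per SMACOF iteration for the raw
  stress; the normalized stress-1 trace is asserted non-increasing to 10⁻⁹,
  which holds across the tested regime.
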