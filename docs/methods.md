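# Methods

## Scope and model

`milklip` implements a combined shotgun-MS and GC workflow for milk lipids:

1. **Mass model.** Species formulas are assembled as backbone residue +
   Σ free fatty acids − one water per ester/amide bond. Backbone residues:
   glycerol (TAG), glycerophosphocholine (PC), glycerophosphoethanolamine
   (PE), glycerophosphoserine (PS), glycerophosphoinositol (PI); SM is a
   sphingoid long-chain base (LCB) + amide-linked FA + a phosphocholine
   residue (C5H12NO3P). Atomic monoisotopic masses live in one versioned
   plain-text table (`milklip/data/elements.tsv`); ion m/z always includes
   the electron mass (one subtracted per positive charge, added per
   negative charge). This rule is what makes the phosphocholine fragment
   compute to 184.0733 — atoms alone give 184.0739 — and it puts the
   ammoniated TAG 52:2 precursor at 876.8015.

2. **Acquisition geometry.** One centroided MS/MS spectrum per 1-amu
   precursor step across m/z 400–1000, fragments restricted to 150–1000,
   both polarities. The isolation window of step *s* is [s − 0.5, s + 0.5);
   a species is co-isolated by a step iff its precursor m/z lies in that
   window. Identification is MS/MS-only; no precursor survey scan is
   modeled or required.

3. **Identification rules.**
   * TAG (positive, [M+NH4]+): per-FA neutral-loss fragments at
     precursor − (FA + NH3). Evidence FAs are restricted to pool members
     whose complement (the remaining two acyls) is reachable from the pool;
     at least 2 distinct neutral losses are required — a single-fragment
     TAG is indistinguishable from noise. The FA pool defaults to 4–20
     carbons with 0–5 double bonds.
   * Glycerophospholipids (negative; PE/PS/PI as [M−H]−, PC as [M+HCOO]−):
     all distinct FA carboxylate anions of a candidate pair must match in
     the step of the candidate's precursor; the pair's totals equal the
     precursor sum composition by construction. PS additionally requires
     the serine-loss fragment (precursor − 87.0320). The
     glycerophospholipid pool spans 12–22 carbons (no short-chain moieties).
   * PC/SM sum species (positive, [M+H]+): the 184.0733 headgroup ion plus
     a candidate precursor in the step window.
   * Internal standards (spike sheet) are identified by direct molecular
     matching and flagged; their identity is known a priori, so the
     minimum-fragment threshold does not apply (the TAG standard
     17:1–17:1–17:1 has exactly one distinct neutral loss).

4. **Quantification.** pmol(species) = spike_pmol(class standard) ×
   Σ evidence(species) / Σ evidence(standard), with the evidence sum over
   neutral-loss intensities (TAG), FA-anion intensities
   (glycerophospholipids) or the headgroup intensity (PC/SM sum level).
   Standards are excluded from every composition denominator. The estimate
   is a ratio, hence invariant under global intensity scaling and exactly
   linear in a species' own fragment intensities. No response-factor or
   isotope-pattern correction is applied; the simulator's default response
   factor is 1 per class (configurable, for robustness tests).

5. **Indices.** The FA index of a TAG sum composition is the share of each
   FA's neutral-loss intensity within the species (rows sum to 1). The FA
   profile weights index rows by pmol; the unsaturation index bins the
   profile by double-bond count, capped at 5 (configurable). Isomeric TAG
   stoichiometry is deliberately not deconvolved: with milk-grade isomer
   complexity, fragmentation-behavior assumptions are not trustworthy, and
   the FA index is the stated alternative.

6. **GC-FAME.** Peaks (rt, area) are assigned to the nearest library FAME
   within ±0.1 min (ties to the lower retention time), quantified by
   per-FAME OLS calibration of amount on area (intercept retained — these
   are curves, not one-point response factors), normalized to percentages,
   and compared across groups by one-way ANOVA with Fisher's LSD at
   α = 0.01 (pairwise t-tests on the pooled MSE). Percentages are
   mole-based; GC cannot see FAs below 10 carbons, while the MS side can —
   the short-chain "blind spot" the comparison module surfaces.

## Key parameters

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| fragment match tolerance | 0.01 | m/z | TOF-like accuracy; absolute, configurable |
| min distinct TAG NL fragments | 2 | count | below this, indistinguishable from noise |
| TAG FA pool | 4–20 C, 0–5 db | — | observed milk TAG moiety range |
| GPL FA pool | 12–22 C, 0–5 db | — | no short-chain glycerophospholipids detected |
| headgroup candidate db cap | 6 | count | see "degeneracies" below |
| GC assignment window | 0.1 | min | half the guaranteed library spacing |
| GC run time | 58 | min | instrument program length |
| LSD alpha | 0.01 | — | significance level used for flagging |
| detector response (simulator) | 100 | counts/pmol | arbitrary global scale; cancels in ratios |

## Resolved degeneracies and tie-breaks

* **PC/PS isobars.** [PC n:d + HCOO]− and [PS (n+3):(d−1) − H]− share one
  elemental formula, so FA anions in a PS step can satisfy a degenerate
  (repeated-chain) PC candidate. Molecular PC identifications therefore
  require cross-polarity confirmation: the phosphocholine ion must be
  present at the PC's [M+H]+ step (skipped only when no positive spectra
  exist at all). A PC found in both modes keeps a single record at
  molecular level.
* **Headgroup-route candidates.** Sum compositions differing by +1 C/+7 db
  sit 0.094 m/z apart — inside one isolation window. Candidates for
  184.0733-based PC/SM identification are capped at 6 total double bonds,
  a curation choice matching milk PC/SM target lists; for TAG the analogous
  ambiguity is resolved by the fragment m/z themselves (the competing
  candidates' predicted losses differ by ≥ 0.09).
* **Peak assignment.** Each predicted fragment takes the single nearest
  peak within tolerance; exact distance ties go to the lower m/z. One peak
  may serve several predictions only when the predictions themselves are
  closer than the tolerance (co-isolation interference of type II is not
  corrected — a documented limitation).
* **GC ties.** Peaks equidistant between two library FAMEs go to the lower
  retention time; libraries with entries closer than twice the window are
  rejected outright.

## The synthetic-data generator

The generator is the package's study-condition definition, not a test
helper. Fixtures: `human1`/`human2` (TAG > 97 mol%, long-chain unsaturated,
~1.6% short-chain FA share; `human2` applies a seeded ±10% perturbation to
TAG abundances, mimicking inter-individual variation), `cow` (TAG-dominated
with a short-chain arm: ~12.9% of TAG-esterified FAs have 4–10 carbons) and
`lacprodan` (a phospholipid-enriched formula concentrate: classes
25/35/18/8/9/5 mol% TAG/PE/PC/SM/PS/PI, dominated within class by
PC 16:0–18:1 at 23 mol%, PE 18:1–18:1 at 34, PI 18:0–18:1 at 39 and
PS 18:0–18:1 at 38). All fixtures put FA 16:0 + 18:1 at 55–60% of the
GC-quantifiable (≥ 10 C) FA pool. These values were calibrated once against
the characteristics the compositions are meant to emulate and then frozen.

Forward model: each species contributes total intensity
100 counts/pmol × response factor at its precursor's step/polarity, split
*per esterified chain* (each of a TAG's three chains carries an equal
share, so the neutral loss of a twice-esterified FA is twice as intense);
PS's serine-loss fragment takes one extra equal share; headgroup-detected
species put the full budget on the 184.0733 ion. An alternative —
splitting evenly across *distinct* fragments — was rejected because it
breaks the exact agreement between the chain-derived GC percentages and
the fragment-derived MS FA profile for species with repeated chains; the
per-chain rule keeps GC and MS as two exact views of one ground truth at
zero noise, which is the invariant the test suite pins at 1e-9. Real
chain-length- and position-dependent fragmentation biases are *not*
modeled by default (an optional per-class response factor exists for
robustness experiments); passing tests therefore demonstrate correctness
of the bookkeeping, not robustness to real instrument bias.

Noise: Gaussian m/z jitter (ppm scale), multiplicative log-normal intensity
noise parameterized by CV (mean-one), and Poisson-count uniform baseline
peaks. All draws come from one seeded generator consumed in a fixed order,
so identical seeds give byte-identical experiment files, and the jitter
offsets scale proportionally with the ppm setting — which makes
identification recall provably non-increasing in the jitter scale at fixed
tolerance.

GC simulation inverts the calibration curves on per-chain FA amounts
(≥ 10 C only), with retention-time jitter bounded at 0.02 min — small
enough never to cross the 0.1-min assignment window, so GC round trips are
exact by construction while still exercising the assignment logic.

## Problem sizes and numerical choices

The acceptance script runs 20 seeded noisy simulations per fixture
(~1200 potential spectra each, full candidate enumeration: ~700 TAG sum
compositions, ~8800 glycerophospholipid pairs), chosen to give stable
medians for the recovered class compositions. Fragment intensities are kept
as floats end to end; fixture files round m/z to 4 decimals and intensities
to 1 decimal, so byte determinism holds while matching (tolerance 0.01)
is unaffected. Exact-equality claims (round trips at 1e-6/1e-9) are made
on in-memory objects, not on rounded files.

## Known limitations

* No isotope-pattern correction, no response-factor calibration, no FDR
  model or decoy search.
* sn-positions, double-bond positions and cis/trans configuration are
  outside the MS model (the GC side carries positional suffixes as opaque
  text only).
* Type-II co-isolation interference is not corrected: shared peaks may
  support several precursors.
* Ether lipids, lyso-species and classes beyond TAG/PC/PE/PS/PI/SM are not
  modeled; SM is fixed to a dihydroxy LCB backbone and quantified at sum
  level (the headgroup fragment carries no FA information).
* mzML ingest covers centroided MS2 scans with standard binary encodings
  only; the JSON-lines fixture format is canonical.
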