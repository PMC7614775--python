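# Methods

`cysengage` implements the computational core of a covalent-fragment
chemoproteomics campaign: quantifying compound engagement of individual
protein cysteines from multiplexed activity-based protein profiling
(ABPP) data, fitting concentration- and time-resolved engagement curves,
and normalizing the companion cell-based assays. This note records the
models, the numerical choices, and what the synthetic test surface does
and does not establish.

## Competition quantification (TMT-ABPP)

Cells or lysates are treated with vehicle (DMSO) or an electrophilic
compound, surviving reactive cysteines are labeled with a desthiobiotin
probe (IA-DTB), and labeled peptides are quantified across the reporter
channels of an isobaric (TMT) multiplex. A compound that covalently
occupies a cysteine blocks probe labeling, so the channel signal drops in
proportion to occupancy.

For each peptide-spectrum match (PSM), every channel's reporter intensity
is divided by the mean of the DMSO channels, giving a per-channel
*fraction of DMSO*. PSMs are filtered before aggregation:

| rule | retention condition | note |
|---|---|---|
| reverse hit | not a reversed-database match | search artifact |
| tryptic | fully tryptic sequence (K/R termini) | search constraint |
| length | peptide ≥ 6 residues | search constraint |
| DMSO sum | summed DMSO intensity ≥ 10,000 | exclusion is strict `< 10,000` |
| DMSO CV | CV ≤ 0.5 | sample SD (ddof = 1) / mean; strict `> 0.5` excluded |

Exclusions are tallied once per PSM under the first failing rule, in the
fixed order above, so report counts are reproducible and sum to the
input size. Boundary values (sum exactly 10,000, CV exactly 0.5) are
retained.

Retained fractions are averaged over a condition's replicate channels
(duplicate channels in the default design), then aggregated over PSMs per
(protein, cysteine residue) site. The aggregation statistic is the
median (robust to a single outlying PSM; the mean is available as an
option). Whether replicate averaging precedes or follows PSM aggregation
is an open design point in the field; this package averages replicates
first — for duplicate channels and ≤2 PSMs the two orders coincide.
Peptides carrying more than one labeled cysteine (e.g. a tryptic peptide
spanning two nearby cysteines) cannot be resolved by the reporter signal
alone: the quantification is emitted for every labeled residue with an
`ambiguous` flag, and resolution is left to orthogonal evidence such as
mutagenesis.

The site-level **competition ratio** is R = 1 / fraction, and
**engagement** is `100 · (1 − 1/R)` percent. Ratios above a cap
(default 20, a common convention that acknowledges the compressed dynamic
range of reporter quantification) are reported at the cap, with fraction
and engagement recomputed from the capped value so the identity holds on
every output row. A site is called *engaged* when its capped ratio is at
least 4 — equivalently ≥ 75% loss of probe signal versus DMSO. The cap
is applied before thresholding.

## Covalent occupancy model (synthetic truth)

The generator plants engagement using the standard two-step model of
irreversible covalent inhibition: reversible recognition (constant K_I,
μM) followed by bond formation (rate k_inact, min⁻¹). After
preincubation for time t at concentration C,

    occupancy(C, t) = occ_max · (1 − exp(−k_inact · t · C / (K_I + C))).

The concentration of half-maximal engagement therefore falls with
preincubation time:

    TE50(t) = K_I · ln 2 / (k_inact · t − ln 2)   (occ_max = 1, k_inact·t > ln 2),

which is the closed-form oracle used throughout the tests (verified
against numeric root-finding to 1e−6 relative). When k_inact·t ≤ ln 2,
occupancy never reaches 50% and the TE50 is undefined; the function
raises rather than extrapolating. Defaults: k_inact = 0.08 min⁻¹ and a
60-minute preincubation (the usual in vitro engagement protocol),
placing k_inact·t ≈ 4.8, deep enough past ln 2 that dose curves saturate
within a practical dilution series; planted sites are parameterized by
their TE50, with K_I derived through the closed-form inverse.

### Noise and nuisance structure

Reporter noise is multiplicative log-normal per channel with unit mean
and configurable CV (default 0.10) — the natural first-order model for
reporter-ion intensity scatter. PSM counts per site are 1 + Poisson(λ),
λ = 2 by default. QC-violating PSMs are injected at configurable,
mutually exclusive per-row rates; each is constructed to trip exactly
its intended rule at zero noise (low-intensity rows have their DMSO sum
rescaled to 5,000; high-CV rows get a 2×/0.05× DMSO pattern, CV ≈ 1.3),
and the ledger records every injection, so filter exactness can be
audited record-for-record. Under nonzero noise an injected violation
could in principle trip a different rule first; exactness claims are
therefore stated at zero noise.

All randomness in a generated table flows from one `numpy` Generator
seeded by a single integer; sites are processed in order, and per site
the peptide is drawn first, then per PSM the violation label, then the
channel noise vector. Identical seeds give identical tables.

What the generator does **not** emulate: co-isolation interference,
isotopic impurity leakage between TMT channels, missing channels,
chromatographic batch effects, peptide identification error, or
between-site intensity correlation. Passing tests establish the
correctness of the engagement arithmetic and calling logic under the
stated noise model, not robustness to these real-data pathologies.

## Dose-response fitting

Engagement (or percent-of-control inhibition) versus concentration is
fitted to the four-parameter logistic

    y(x) = bottom + (top − bottom) / (1 + (x / midpoint)^hill)

by bounded nonlinear least squares in log10-concentration space
(`scipy.optimize.least_squares`, trust-region reflective). Defaults for
percent-scale readouts: bottom ∈ [0, 20], top ∈ [80, 120], hill ∈
[0.3, 5]; all overridable. Starting values: bottom/top from the extreme
responses, hill = 1, midpoint at the tested concentration whose response
is nearest half-maximal. The log10-midpoint is allowed two decades
beyond the tested span; fits landing outside the span are flagged
`extrapolated` rather than suppressed, mirroring the ">" potency-bound
convention. Curve orientation (engagement rises with dose,
percent-of-control falls) is detected from the data and the reported
hill is always positive. The fit is deterministic and scale-equivariant
(scaling all concentrations scales the midpoint).

Because the covalent occupancy curve is not exactly logistic, the fitted
midpoint tracks the kinetic TE50 only where occupancy saturates within
the tested range (k_inact·t ≫ ln 2); at short preincubation the
occupancy plateau falls below the percent-scale top constraint and the
two quantities are not comparable. The time-series tests assert the
strict decrease of fitted midpoints across 10/30/60-minute
preincubations, and closed-form agreement only in the saturating regime.

Confidence intervals use a case-resampling bootstrap over the measured
points with a percentile interval at *expanded* levels (Hesterberg,
Am. Stat. 69:371, 2015): the nominal ±1.96 endpoints are widened by the
t/normal quantile ratio at n − 1 degrees of freedom (for a duplicate
7-point series, percentiles 1.25/98.75 instead of 2.5/97.5). Plain
percentile intervals undercover for short dose series — ≈ 88% observed
at nominal 95% for this design at 10% CV in our calibration simulations,
a known small-sample deficiency — while the expanded interval restores
≈ 94% coverage in the same simulations. Resamples that collapse below
four distinct concentrations are skipped and counted. Intervals are
seeded and reproducible; at zero noise the interval collapses onto the
point estimate.

## Targeted quantification

PRM: a site's signal in a sample is the sum of six pre-selected
fragment-ion peak areas (order-invariant by construction); engagement is
computed against the mean of the vehicle samples, sharing the fraction /
ratio / engagement identities with the multiplexed pipeline. No
per-fragment outlier rejection is applied. Targeted TMT applies a gate
of at least ten summed signal-to-noise across the control (DMSO)
channels — inclusive at exactly ten — then routes the surviving
records through the same competition arithmetic with S/N standing in
for intensity.

## Functional-assay normalizations

* **HTRF**: per-well ratio (665 nm / 620 nm) × 10⁴. The basal ratio —
  the mean of the unstimulated DMSO wells (two per plate) — is
  subtracted uniformly from all wells, and stimulated wells are scaled
  to percent of the basal-subtracted mean of the stimulated DMSO
  controls (five per plate). Applying the basal subtraction to the
  stimulated controls as well is required for the percent formula to
  close at 100 for the controls themselves. A plate whose stimulation
  window is not positive is rejected as an assay failure. Values are not
  clipped; a well below basal is legitimately negative.
* **Densitometry**: background-corrected band intensity as a percent of
  the mean background-corrected control lanes, per target.
* **qPCR**: 2^−ΔΔCt fold change against a reference gene and control
  sample; reciprocal by construction (swapping sample and control
  inverts the fold change).
* **Trans-phosphorylation**: phospho-signal of a kinase-dead recipient
  construct, normalized to the native-cysteine reference pair for DMSO
  efficiency and to each pair's own DMSO baseline for compound effect.
  Additional normalization to total recipient protein loading is not
  applied (left to upstream densitometry if desired).

All percent-of-control operations return exactly 100 on their own
control and are invariant to rescaling every raw signal on a
plate/membrane by a common positive factor.

## Selectivity reporting

Sites of one condition are ranked by capped competition ratio,
descending, ties broken lexicographically by site identifier — a fixed,
deterministic rule. Engaged sites outside the declared-target list are
reported as off-targets. The pipeline bundle records provenance (config
hash, seed, package version, table sizes) so a report can be regenerated
from saved intermediates byte-identically.

## Problem sizes

The shipped tests and the reproduction script run at desk scale: site
panels of 40-1,000 cysteines, ~3 PSMs per site (≈ 10⁴ PSMs for the QC
audit), 7-point dose series in duplicate, 100-series bootstrap coverage
simulations at 200 resamples. These sizes were chosen so the full suite
exercises every code path in minutes; the arithmetic itself is
vectorized and indifferent to table size. Proteome-scale claims (tens of
thousands of quantified cysteines) are represented only by these scaled
surrogates.

## Known limitations

* No isotopic-impurity correction or co-isolation modeling; competition
  ratios from real instruments are compressed relative to truth, which
  is one reason for the ratio cap.
* The 4PL midpoint is an operational TE50/IC50; no attempt is made to
  decompose it into k_inact and K_I from progress curves.
* QC exactness against the injection ledger is guaranteed only at zero
  reporter noise.
* Single-channel (non-replicate) conditions are not supported by design;
  the layout requires at least two DMSO channels.
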