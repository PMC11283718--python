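# Methods

This note records the models, defaults and design choices behind each
module, what the synthetic generators do and do not emulate, and the
known limitations.

## Reaction thermodynamics

Species carry standard free energies of formation (kJ/mol); the
reaction free energy is the coefficient-weighted product-minus-reactant
sum. The shipped species table contains exactly the six members of the
thiosulfate/arsenate couple with ΔGf° = −714 (HAsO4²⁻), −647 (S2O3²⁻),
−237 (H2O), −640 (H3AsO3⁰), −745 (SO4²⁻) and −157 (OH⁻) kJ/mol. Direct
summation gives **+170 kJ/mol** for the displayed reaction; the value
printed alongside the equation in the original report is 172 kJ/mol
with ambiguous sign typesetting. The module always reports the
computed signed value and we document the 2 kJ/mol discrepancy here
rather than matching the printed figure. Note the positive
standard-state value reflects the OH⁻-producing formulation at unit
activities; environmental conditions (circumneutral pH, low product
activities) make the process favourable in situ. No activity,
ionic-strength or temperature corrections are attempted — the module is
a standard-state bookkeeping tool.

Electron accounting uses caller-supplied oxidation states (defaults
shipped for the six species; thiosulfate sulfur is taken at its +2
average). Automatic oxidation-state inference was deliberately
avoided as fragile; a species lacking states makes the electron count
`None` instead of a guess.

## Incubation kinetics

Rates are ordinary-least-squares slopes. The defensible minimal
reading of a "production rate" over a transfer culture is a single OLS
fit over the whole series; a "maximum rate" is the largest-magnitude
slope among sliding windows of k timepoints (default k = 3). A
difference-quotient mode (`mode="diff"`) is available since the original
report does not state whether its maxima derive from window fits or
adjacent-timepoint quotients; window OLS is the default.

Replicates are pooled into one regression for the headline estimate
(the estimate and its stderr come from the pooled fit); per-replicate
slopes feed the two-sided Welch t-tests used for all group comparisons.
The report gives bare P values without naming a test; Welch is the
robust default. No multiple-testing correction is applied by default
(none is applied in the source analyses); Benjamini–Hochberg is
available via `p_adjust="bh"`.

Correlations of site potential with geochemical covariates use Pearson
r, a two-sided t-distribution p-value and a Fisher-z interval at 0.95.
Zero variance yields an explicitly undefined result, never a silent 0.

Window-maximum estimators carry a positive selection bias of roughly
the window-slope standard error (max of several noisy slopes sharing
the true value); at the default operating points this is ~1 μM/g dw/d
on 38, visible in the acceptance outputs and left uncorrected — it is a
property of the estimator, not a bug.

## SIP enrichment

Band intervals are closed on both ends (heavy [1.73, 1.75], light
[1.70, 1.72] g/ml); the verbal "between" of the source is ambiguous and
the closed reading keeps the printed bounds in-band. Fraction-specific
exceptions are expressed only as explicit per-fraction overrides — the
exception rule for the two excepted fractions in the original gradients
is unstated, so nothing is inferred.

The heavy share is computed per replicate gradient
(100 × heavy copies / total copies) and summarised as mean ± sd over
replicates, matching the "16 ± 3%" form; pooling copies before the
ratio is *not* done (the choice between the two is unstated upstream;
per-replicate keeps the replicate as the unit of inference). Shares
over the heavy/light/excluded partition sum to 100 exactly. ASV
significance uses Welch t-tests on untransformed relative abundances;
an arcsine-square-root option exists behind a flag.

## Genome screening

The arsenate-reduction call requires, in conjunction: an *arrA* gene;
the R/KGRY motif anywhere in its protein (no positional constraint —
imposing one would require an alignment the rules don't define); an
*arrB* on the same contig and strand with ≤ 1 intervening gene
(configurable; relaxable to *arrA*-alone with `require_arrb=False`,
since the source screening is not fully explicit on requiring the pair
for reference genomes); and both *arrD* and *arrE* within 3 gene
positions of the pair. The adjacency thresholds are tolerant defaults
for fragmented MAG contigs. *arrA* without a protein sequence makes
the motif check unevaluable and the genome is conservatively classed
`neither` with a warning.

Sulfur oxidation is called from *soxB* presence or a reverse/oxidative
*dsrA*. SOX completeness uses a seven-component soxXYZABCD module
(configurable KO list; "complete" ⇔ 1.0). *dsrA* typing replaces
phylogenetic placement with nearest-reference global-alignment percent
identity (floor 40%, cross-label ties → unknown); the shipped reference
seeds are synthetic sequences that stand in for curated clade
representatives, preserving the classifier's contract at desk scale.
Reverse and oxidative-type dsr are collapsed into one sulfur-oxidation
category, as both function as oxidation markers in the screening rules.
Family labels are consumed from annotation tables; an optional HMMER
domtblout parser assigns each gene its best family by score under an
e-value ceiling of 1e-10, ties broken by score then alphabetically.

## Community quantification

Class precedence: an explicit per-genome screen result overrides
genus-list membership (genus transfer is only justified where *arr*
genes are lineage-conserved). Abundances are treated as already
normalised (TPM-like); only within-sample shares are computed. The
across-sample SOAsRB vs non-S-oxidizing comparison is a paired
two-sided t-test on per-sample share pairs — the two shares of a sample
partition the same total and are intrinsically paired. Per-sample
shares are averaged over samples (a pooled-abundance mode is not the
default; whether the upstream 87% figure is a mean or pooled value is
unstated). Ranking ties break alphabetically for reproducibility.

## Synthetic generators

All generators are pure functions of config + seed (byte-identical
reruns; a single `numpy` generator is passed explicitly, no global
state).

**Incubations**: c(t) = c0 + rate·max(t − lag, 0) plus additive
Gaussian noise truncated at 0 (measurement error); in stoichiometric
mode the As(V)/As(III)/SO4 slopes are locked 4:4:2 so arsenic is
conserved at every timepoint. Scenario defaults encode the study's
operating points: transfer cultures at 26/13 μM/d with σ = 2/3 μM over
a 30-day, 7-point grid (the initial As(V) pool is sized at 1000 μM so
the substrate never limits over the window); donor comparison at
38/45/1.4 μM/g dw/d with a 3-day lag for donor treatments, σ = 2 (donor)
and 0.14 (control, 10% of slope); a six-site survey spanning
43…4.4 μM/g dw/d with σ = 4 (only the extremes are reported upstream;
the intermediate site values are a realistic spread chosen once).
Replicate counts default to 5 (the activity-incubation setup) at the
config level and 3 (triplicates) in the scenario factories used for
recovery studies.

**SIP gradients**: per taxon, DNA mass over the 12-fraction buoyant-
density grid (1.69–1.76 g/ml) is a discretised Gaussian (σ_d = 0.008
g/ml) centred at 1.71 for unlabelled DNA and shifted by Δ = 0.035 g/ml
for the labelled portion — Δ chosen so labelled mass centres inside the
heavy band starting from the light band; per-fraction copies get
multiplicative lognormal qPCR noise (σ_log = 0.15). The labelled-taxon
abundance and its *arrA* dosage are solved in closed form so the
no-noise heavy-band mass equals the target shares (16% SSU, 15% arrA in
the fully active labelled treatment); the heavy-band mass is linear in
the labelled fraction p, so p = (target − h0)/(h1 − h0). Controls
missing one substrate get a scaled `activity` (3/16 and 4/16),
reproducing their reduced incorporation with a single scalar. The ASV
table derives from the same taxon composition per fraction band. Mass
pushed past the grid edge is truncated (renormalised) with a warning.

**Genomes**: single-contig annotations with non-overlapping 1-based
coordinates; ArrA proteins are first scrubbed of any chance motif, then
(for motif-positive genomes) given one implanted R/KGRY; dsrA proteins
are the synthetic reference seeds mutated at 10% of sites; operon
layout is arrD–arrA–arrB–arrE on one strand when flanked. Contradictory
feature flags (motif without arrA) are rejected.

**Quant tables**: group proportions are exact in no-noise mode or drawn
from Dirichlet(concentration × share-vector); larger concentrations
shrink across-sample spread monotonically.

What the generators do **not** emulate: substrate depletion/saturation
kinetics (no Monod), gradient physics and fraction-volume artefacts,
chimeras/contamination, read-level sequencing error, compositional
coupling between taxa beyond closure, and database incompleteness in
screening. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated error models, not robustness to
every artefact of real gradient or sequencing data.

## Numerical choices and degenerate inputs

Welch tests on two identical constant groups return p = 1 explicitly
(scipy yields NaN); zero-total shares are NaN-flagged "undefined", not
0; all-equal timepoints and windows shorter than 2 points raise; rates
are never clipped at zero (truncation lives in the generator only,
as a property of the measurement, not the estimator). Global
alignments use match +1 / mismatch −1 / gap open −2 / extend −0.5;
identity = identical columns / alignment length.

## Problem sizes

Recovery studies use 200 simulations for rate operating points, 100
draws for SIP share recovery, 1000 null draws for test calibration, and
17 synthetic samples for the community aggregate — sizes at which
Monte-Carlo standard errors are well below the acceptance bands while
the full suite runs in seconds on one CPU.

## Known limitations

Thermodynamics is standard-state only. Kinetics is linear-phase OLS;
lag estimation is not modelled (the window maximum absorbs it).
dsr typing by nearest-reference identity degrades gracefully to
`unknown` but cannot resolve genuinely novel clades. The screen trusts
upstream annotations; it does not re-run HMM searches. Genus-level
class transfer in quantification inherits any misassignment in the
genus lists supplied to it.
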