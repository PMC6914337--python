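# Methods

## The measurement model

A ¹⁵N pulse-labeling experiment yields, for every tryptic peptide, two
co-eluting MS1 signals: the light form from protein made before the
label switch (natural isotopic abundance, ≥ 99.6% ¹⁴N) and the heavy
form from protein made after it (nitrogen pool at the dietary ¹⁵N
enrichment). Because the two forms are chemically identical they share
the chromatographic profile exactly; the per-scan intensity ratio
between the channels is therefore constant across the elution peak and
equals the old/new abundance ratio of the parent protein. Everything
the pipeline does rests on that invariance.

### Isotope envelopes

A peptide's elemental composition is the sum of its residue formulas
plus one water, with fixed modifications added per residue (default:
carbamidomethyl on Cys, +57.02146 Da, composition C2H3NO). Envelopes
are computed by expanding each element's isotopologue distribution on
nominal-mass-offset bins (exact multinomial via convolution
exponentiation) and convolving across elements. Bins carry the
abundance-weighted mean mass of their isotopologues — an *aggregate*
envelope. At the 60K Orbitrap resolution typical of MS1 surveys the
fine structure inside a unit-mass bin is unresolved, so the aggregate
quantity is what the instrument measures; fine isotopic structure is
deliberately out of scope.

For the heavy channel the nitrogen isotope distribution is replaced by
(1−e, e) where e is the ¹⁵N atom enrichment. **Default e = 0.99.** The
labeling literature quotes serum *protein* labeling above 99% after a
full labeling course; the atom-level enrichment of the diet is not
usually reported, so 0.99 is a conservative reading and the value is
configurable everywhere it enters (envelopes, channel assignment,
simulation). The heavy reference mass used for channel assignment is
the fully ¹⁵N-substituted monoisotopic mass, light mono + N × 0.9970349
Da; at e ≥ 0.99 and N ≥ 6 the all-¹⁵N isotopologue dominates the heavy
envelope, so this is the peak a search engine would match.

Numerical choices: the full binned distribution conserves probability
to < 1e-9 (asserted at computation time); bins below 1e-13 probability
are dropped because their weighted masses lose floating-point meaning,
which costs orders of magnitude less abundance than the conservation
guarantee. Envelopes are truncated to the top k = 3 peaks per channel
(renormalized, flagged): three peaks capture ≥ 95% of the intensity of
tryptic-size peptides while keeping the XIC windows narrow enough to
limit interference from unrelated species.

Isotope masses and natural abundances (IUPAC/CIAAW 2013) and the
residue formula table ship as documented plain-text files in
`silamq/data/`; the 15N−14N spacing implied by the table is exactly
0.9970349 Da.

### XIC extraction and the peptide ratio

For each identified (sequence, charge) the two channels' top-k envelope
peaks become m/z target sets. Every MS1 scan within ±60 s (default
`rt_window` 120 s) of the identifying PSM contributes the sum of
centroid intensities within 10 ppm of any target, per channel; the ppm
boundary is inclusive, and a centroid inside two overlapping target
windows is counted once. Scans with zero signal stay in the trace —
they carry profile information.

The ratio estimate is the slope of the zero-intercept least-squares fit
of light on heavy intensity, `r̂ = Σ L_i H_i / Σ H_i²`, over scans where
at least one channel is above its noise floor. This makes the reported
number directly the ¹⁴N/¹⁵N ratio. Zero-intercept least squares is not
symmetric in its arguments: swapping the channels gives exactly the
inverse only for perfectly proportional data. On noiseless traces the
product of the two orientations is 1 (tested); under noise the
asymmetry is second-order, and a symmetric geometric-mean estimator
(`sqrt(Σ L² / Σ H²)`) is available via `estimator: gmr` for users who
prefer orientation invariance.

Quality control is the Pearson correlation between the paired per-scan
profiles: a record passes only when r > 0.5 (strictly) and at least 3
scans were used. r rather than r² is used, and the correlation is
computed on the same scans as the fit; it is undefined (flagged, not
zero) when fewer than 3 points exist or a channel is constant.

**Channel presence / noise floor.** "¹⁴N-only" calls are detection
claims, so the rule is explicit: the noise floor of a channel is the
median of its nonzero intensities in the flanking 25% of scans on each
side of the extraction window (zero when the flanks are silent or the
trace is too short to have flanks), and a channel is present when its
peak exceeds 3× that floor (`presence_snr`, configurable). Light
present with heavy absent yields LIGHT_ONLY evidence, and symmetrically.

### Identification filtering and FDR

Filters mirror classic DTASelect-style post-search criteria: peptide
length ≥ 6, at least one tryptic end (cleavage after K/R, blocked by a
following proline — the conventional trypsin rule, applied here
explicitly; protein termini count), unlimited missed cleavages unless
bounded, |precursor error| ≤ 10 ppm, charges 2–6. The peptide score
threshold is the *loosest* threshold whose accepted set satisfies the
FDR target, with FDR estimated as decoys/targets against a
reversed-sequence decoy database (`DECOY_` prefix; the paired
2d/(t+d) estimator is available as an option). Protein-level FDR uses
best-peptide-score ranking and decoy counting at the protein level.
The peptide FDR target defaults to 0.01; the stricter 0.001 some filter
configurations quote is one config key away. Every rejected PSM carries
a reason code; nothing is silently dropped.

### Protein rollup

PASS peptide ratios are pooled per accession (a shared peptide counts
for every protein it maps to; razor attribution is out of scope). With
more than two peptides, iterative two-sided Grubbs outlier removal runs
at p < 0.01 on **log-ratios** — ratio noise is multiplicative, so the
normality assumption behind the Grubbs statistic is only plausible in
log space. The critical value comes from the Student-t quantile formula
G = (n−1)/√n · √(t²/(n−2+t²)), t = t(1−α/2n, n−2). The composite is the
intensity-weighted geometric mean of the survivors (weights = light +
heavy XIC area, so weak measurements are down-weighted); an unweighted
median is available by configuration.

Composites are clamped into [0.05, 20] — with one channel near the
detection limit the raw quotient is mathematically unbounded, and the
caps mark "beyond the measurable dynamic range" rather than a value.
The cortex/nucleus comparison raises the ceiling to 100 because nuclear
proteins can be essentially all-¹⁴N; ratio ties at the ceiling are
reported as ties. Caps apply at the protein level, not the peptide
level.

Classification: QUANTIFIED (≥ 1 PASS ratio), LIGHT_ONLY / HEAVY_ONLY
(all peptide evidence in one channel), and AMBIGUOUS for proteins with
both channels seen but no ratio of passing quality. The three-way
fractions reported by `tissue_compare` exclude AMBIGUOUS (it is counted
alongside), so they sum to 1 by construction. Spectral counts (PSMs per
channel per protein) serve as the abundance proxy for the
most-abundant-¹⁴N-only ranking, with accession as the deterministic
tie-break.

## The synthetic-data generator

The generator emulates exactly the features the method depends on:
Gaussian elution profiles with center and width shared between channels
(width 20–60 s ≈ 4σ, drawn per peptide); per-channel areas set by the
planted ratio, with UNLABELED and FULLY_LABELED sentinel states
injecting zero signal in one channel; top-k envelope peaks placed at
the charge-state m/z within the 300–1500 m/z scan range; multiplicative
lognormal noise per centroid (unit mean, parameterized by CV —
intensities are positive, so Gaussian noise would misbehave near zero)
plus an optional additive floor of random centroids; one PSM per
detectable channel at the apex scan. Planted ratios default to
log-uniform over [0.05, 20], matching the dynamic range the caps
define. All outputs are pure functions of (config, seed) and
byte-identical across reruns.

An interference guard drops peptides whose targets fall within twice
the ppm tolerance of a co-eluting, already placed peptide. Without it
the noiseless closed loop cannot be exact, because the single-peptide
XIC model does not deconvolve overlapping envelopes — a limitation the
real pipeline shares on real data.

What the generator does **not** emulate — and hence what passing tests
cannot show about real data: chromatographic drift and tailing,
envelope overlap between unrelated peptides (excluded by the guard),
intermediate/partial labeling within single molecules, in-source
fragmentation, missing or wrong identifications, and MS2-level effects.
Synthetic validation demonstrates that the estimator and its filters
are correct and calibrated under the model's own assumptions, not that
the assumptions hold on any particular instrument run.

## Validation sizes and outcomes

The test suite and `scripts/acceptance.py` use problem sizes chosen to
exercise every code path while staying desk-scale: the noiseless closed
loop runs 15 proteins (≈ 100 peptides, 1500 scans) and recovers planted
ratios at float precision (~1e-15 relative); the statistical check runs
50 proteins × 10 seeds at CV 0.10 and observes ≥ 95% of quantified
proteins within 15% of truth (median relative error well under 1%);
Grubbs decisions agree with a brute-force reimplementation on 1000
random inputs; the null FDR simulation (20 seeds, 250 targets + 250
decoys) estimates FDR ≈ 1 as it must when no identification is real.

## Known limitations

* Single-timepoint ratios only: no kinetic (rate-constant / half-life)
  fitting.
* Centroid MS1 input assumed; no peak-picking of profile data.
* No cross-run retention alignment; each run is quantified alone.
* Fixed modifications only; variable modifications (e.g. deamidation)
  are not modeled, and peptides carrying them are simply not matched.
* Elements beyond CHNOS are not in the constants table.
* Protein inference is shared-accession assignment; no parsimony or
  protein grouping.
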