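# Methods

This note records the statistical models implemented in crgpipe, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical and design decisions
made where more than one defensible choice existed.

## Pooled barcode fitness scoring

The model behind the scoring stage is multiplicative: a tag's hybridization
intensity is its baseline abundance scaled by 2^f under drug (f the log2
fitness effect) and by log-normal measurement noise. Scoring inverts this
model in four steps.

1. **Quantile normalization** across arrays. The reference distribution is
   the vector of row means of column-sorted data; each column's values are
   replaced by the reference value at their rank. Ties receive the mean of
   the tied reference values (linear interpolation at the average rank).
   With tied values the classical invariant "all columns share the same
   sorted values" holds only approximately; it is exact for tie-free data.
   Rank normalization is not free: a true global shift (many strains
   depleted on the drug arrays only) is partially attenuated, most strongly
   at the extremes of the intensity distribution, because the reference
   mixes drug and control quantiles. On the standard recovery simulation
   this attenuation is about 0.06–0.09 log2 units at f = −1. It is the
   price of robustness to array-wide intensity artifacts, and it is why the
   noiseless model-inversion checks in the test suite bypass normalization
   while all noisy-recovery checks run the full chain.
2. **Tag collapse**: the mean over a strain's uptag/dntag per array. The two
   tags are modelled with independent baselines; averaging them reduces
   per-array noise by √2.
3. **Outlier omission** per strain × condition: with n ≥ 3 replicates,
   values more than one sample SD (ddof = 1) from the replicate mean are
   removed in a single pass; with n ≤ 2 nothing is removed. At least one
   value always survives (no point can be farther than one SD from the mean
   if all points were). The rule runs after normalization; the order is
   configurable.
4. **Score and test**: f = log2(mean drug / mean control) of the retained
   values, so a growth defect is negative. Intensities are floored at half
   the smallest positive value before logs. With equal replicate counts the
   P-value is a two-sided one-sample t-test of the replicate-wise log2
   ratios (paired by replicate index) against zero; with unequal counts it
   falls back to an unpaired two-sample t-test on log2 intensities. Exactly
   constant differences short-circuit to p = 1 (all zero) or p = 0
   (constant non-zero), which keeps noiseless simulations well-defined.
   Calls: sensitive iff f < −1 and p < 0.05; resistant iff f > +1 and
   p < 0.05. The replicate-reproducibility r reported with each table is
   the mean pairwise Pearson correlation of per-replicate score vectors.

**Recovery limits.** On the standard simulation (1000 strains, 50 injected
at f = −1, noise SD 0.25 log2, 3+3 replicates) the mean recovered score of
the injected set is ≈ −0.93 and the null false-positive rate ≈ 0.05. The
*classification* recall of that injected set is only ~30 %, and necessarily
so: the injected effect sits exactly on the −1 calling threshold, so an
estimator centred on the truth can put at most half the strains past the
threshold, before the p < 0.05 requirement and the normalization
attenuation. Threshold-based calling only recovers effects that clear the
threshold with margin: at f = −2 under the same noise, recall is 98–100 %.
The interaction-recovery simulations therefore inject f = −2 — a defect a
screener would describe as clearly sensitive, not borderline.

## Interaction calling and enrichment

The double-deletion pool (query × genome-wide deletions, grown under drug)
is contrasted with the single-deletion control pool. The interaction class
comes from the double pool alone — sensitive → aggravating, resistant →
alleviating — while query-dependence additionally requires the single
mutant to be uncalled at the stricter α = 0.025 (two-sided; one- vs
two-sided is not determined by the procedure's description, and two-sided is
the conservative reading). A gene sensitive in both pools is thus an
aggravating interaction but not query-dependent.

Quantitative SGA scores use the multiplicative neutral expectation:
ε = W_ab − W_a·W_b, positive above +0.08 and negative below −0.08. The
negative threshold is read as ε < −0.08, symmetric with the positive rule
(reading it as ε < +0.08 would overlap the positive band). When replicate
screens are supplied, only interactions whose class agrees across screens
are kept. The full position/batch-corrected SGA scoring machinery is out of
scope; only the ε definition and band are implemented.

MDR filtering removes genes whose deletion causes fitness defects in at
least 20 % of assayed stress conditions (inclusive boundary, per "at
least"); the condition compendium is a user-supplied catalog.

Enrichment uses the upper-tail hypergeometric probability P(X ≥ x) computed
via scipy's log-space survival function (exact agreement with draw
enumeration is asserted in the tests for all N ≤ 12). Bonferroni correction
multiplies by the number of categories tested — standard practice — with a
`correct_by="genes"` option for the literal multiply-by-gene-count variant
some enrichment services describe. Significance is judged on the raw P at a
configurable cutoff (default 0.01) with the corrected value reported
alongside.

## Tiling-array transcriptomics

ORF intervals come from GFF3 (1-based inclusive); a probe belongs to an ORF
iff its interval is fully contained in the ORF interval on the same
chromosome. Containment rather than midpoint overlap is unambiguous for
25-mer probes; assignment is strand-agnostic by default because tiling
arrays interrogate both strands (a `stranded` flag exists). Probes matching
several overlapping ORFs are assigned to all and flagged ambiguous.

ORF expression is the unweighted mean of assigned probe log2 intensities
per array, quantile-normalized across arrays at the ORF level before
comparison (probe-level normalization is available by normalizing the probe
table first; ORF level is the default because the downstream statistics
operate on ORF summaries). Differential expression: log2 fc as the
difference of condition means (values are already log2), two-sided
Student's t, calls at |fc| > 1 and P < 0.05. With fewer than two replicates
per condition the P-value is undefined and the record flagged. ESR genes
are flagged and excluded from the enrichment input; the ESR list is a plain
gene-id file supplied by the user (the canonical stress-response gene set
is distributed with its original publication, not re-packaged here).

Clustering is agglomerative with distance d = 1 − Pearson r (range [0, 2])
and unweighted average linkage, computed by scipy's linkage on the
condensed distance matrix after lexicographic row ordering for
deterministic tie-breaking; zero-variance profiles are dropped with a log
message. The test suite checks cophenetic equality against a naive
agglomeration oracle for up to six profiles.

## Lipidomics and qPCR

Lipid species are described as `CLASS[-HYDROXYL] CARBONS:DOUBLEBONDS`
(e.g. `PI 34:1`, `IPC-C 44:0`); -B/-C/-D denote two, three and four
hydroxyl groups and are accepted only on sphingolipid classes. Raw MRM
intensities are divided by the class-matched internal standard in the same
sample (missing or zero standards are hard errors naming species and
sample), making normalized values invariant to per-sample scaling. The drug
response is log2 of the ratio of normalized group means; a zero group mean
yields a flagged NaN rather than ±inf.

Per-species significance uses the Kruskal-Wallis rank test with mid-rank
ties and the standard tie correction (scipy's implementation; the
hand-formula equivalence is asserted in tests). P-values come from the
chi-square approximation with k − 1 df, or from exact enumeration of label
permutations when the total N ≤ 8 (`exact="auto"`). Two caveats matter at
bench-scale sample sizes: with three replicates per group the statistic
takes at most ten distinct values, the chi-square approximation rejects a
true null with probability 0.10 at α = 0.05, and the exact test can never
reject (its smallest attainable P is 0.10). Calibration checks in this
package therefore run at 12 replicates per group, where the chi-square
approximation attains the nominal 5 % rate; single-experiment P-values at
n = 3 should be read as ordinal evidence, not calibrated error rates.

Chain-length stratification calls a species short when its total acyl
carbons are ≤ 32 (two C16 chains) — the cutoff is not a community standard
and is exposed as a parameter — and saturated when it has zero double
bonds.

qPCR: ΔCt = Ct_target − Ct_reference per sample (default reference ACT1),
ΔΔCt = mean ΔCt(condition) − mean ΔCt(calibrator), fold = 2^−ΔΔCt. Adding
a constant to every Ct in a sample cancels. Tests run on the ΔCt scale
(approximately normal, unlike fold changes): paired t for within-strain
treatment contrasts, unpaired for between-strain contrasts. Zero-variance
paired differences are degenerate: identical vectors give (t = 0, p = 1);
an exact constant shift gives p = 0 with a runtime warning, flagged so
callers can treat it as a data artifact.

## Mass-spectrometric product detection

Monoisotopic m/z is the sum of atomic monoisotopic masses (C 12.000000,
H 1.0078250319, O 15.9949146221, N 14.0030740052, S 31.97207069,
P 30.97376151) divided by |charge|. No electron mass is subtracted by
default: for a singly protonated C10H12O4 parent this convention gives
197.0814, whereas subtracting one electron mass gives 197.0808 — both
appear in the literature, and the atomic-sum convention is the package
default with `electron_correction=True` available. The methylation series
derives +CH2 (14.0157), +H2O (18.0106) and +CH2+H2O species from the
parent formula; compositions only — ester vs ring-closed structures cannot
be distinguished from m/z and are out of scope.

EICs sum centroid intensities inside a relative window
center × (1 ± ppm·10⁻⁶) per scan (sum rather than max: robust to centroid
splitting; configurable). Presence of a species in a reaction means the EIC
maximum within ±0.5 min of the complete reaction's apex reaches the
intensity threshold; the apex anchor comes from the complete reaction —
the one containing every component seen across the input — whose absence is
an error. A component is *required* when the species is present in the
complete reaction and absent from the reaction omitting exactly that
component. Verdicts are therefore only as fine-grained as the control
design: components without a matching single-omission control are not
judged.

## Synthetic data: what it does and does not emulate

The generators are pure functions of their spec (seed included) and return
ground truth alongside the data. They reproduce the statistical structure
the analyses assume — multiplicative log-normal intensity noise, per-probe
affinity offsets shared across arrays, mean-preserving log-normal lipid
replicates, per-sample Ct offsets cancelled by ΔCt, Gaussian elution with
ppm-scale mass error and predicate-controlled species presence. They do not
emulate probe-level hybridization physics, spatial array artifacts,
saturation, batch effects, chromatographic tailing or isotope patterns;
passing recovery tests demonstrates the correctness of the analysis logic
under the stated noise model, not robustness to instrument pathologies.

No platform noise magnitudes are prescribed by the assay descriptions, so
defaults were fixed once for test power: pool noise 0.25 log2 units,
tiling probe affinity SD 0.25 with 0.1 measurement noise, lipid CV 0.2
with 3 replicates, Ct SD 0.15 with a 0.5 sample-offset SD, mass error
30 ppm (so ±100 ppm windows capture > 99 % of centroids), retention-time
jitter 0.05 min. Simulation problem sizes used throughout (1000-strain
pools, 3+3 replicate arrays, 1000-species null batteries, ≤ 6-leaf
clustering oracles) were chosen as the smallest sizes at which the
estimated rates have tight enough Monte-Carlo error to be meaningful.

## Known limitations

* Threshold-based sensitivity calling cannot recover effects at the
  threshold itself (see "Recovery limits" above); published hit counts
  obtained this way undercount genes with borderline defects.
* Quantile normalization attenuates genuine global abundance shifts; the
  fitness scores it feeds are conservative for strongly depleted strains.
* The Kruskal-Wallis stage is uncalibrated at n = 3 per group (discrete
  null); its P-values there are ordinal.
* The p-value model for fitness scores assumes log-normal intensity noise;
  heavy-tailed array artifacts are only partially absorbed by the 1-SD
  outlier rule.
* GFF parsing handles the 9-column core only (ID attribute required);
  feature hierarchies, aliases and fasta sections are ignored.
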