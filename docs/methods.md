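# Methods

This note documents the models and procedures implemented in `sstmon`, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions taken where the design was open.

## Acquisition model

A QC injection is a chromatography-free, flow-injection acquisition on an
ESI-TOF instrument in negative mode. The acquisition holds three scan
regimes in document order: chemical background (solvent, contaminants and
two continuously infused lock masses), the QC-mix bolus arriving after an
injection delay, and flow-stop scans that record detector-only counts. The
default chronogram places 120 scans at ~1 Hz: background in scans 0–29,
bolus apex at scan 40, bolus cleared by scan 80, flow stop from scan 95.
The scan rate of the real method is instrument-dependent, so the layout is
configuration (`ChronogramConfig`), and scan selection never relies on it:
the QC scan is found dynamically as the total-ion-current argmax, and the
analysis extends to the two following scans. The background scan defaults
to index 18 (configurable; it must precede the apex), the noise scan to the
third-from-last scan.

mzML 1.1 is the single interchange format. The package carries its own
minimal mzML reader/writer (64-bit uncompressed arrays, MS1 profile scans,
polarity and scan-time metadata) because no suitable Python mzML codec is
assumed at runtime; the writer's output is verified in the test suite
against an independent reader (Bioconductor `mzR`). Intensities are stored
as 64-bit floats regardless of source encoding.

## Expected-peak registry

The QC mixture is modelled as nine negative-mode analytes spanning m/z
100–800. Each contributes its deprotonated monoisotopic ion, M+1 and M+2
isotopologues, and one in-source fragment; one analyte (raffinose) forms a
chloride adduct — 9 + 18 + 1 + 9 = 37 tracked QC peaks. Two lock masses
(homotaurine at 138.0230 Th; the hexakis-fluoropropoxy phosphazine
calibrant, monitored here as its formate adduct at 966.0007 Th) complete
the registry. Apart from fluconazole ([M−H]⁻ at 305.0968 Th, whose fragment
anchors the `fragmentation_305` indicator), the compound list and the
lock-mass species are provisional, chemically plausible defaults: the exact
mixture composition is a lab-specific choice, and the registry is an
editable configuration object.

## Feature extraction

Every peak fit happens inside a ±0.05 Th search window around the
theoretical m/z. The apex is the highest point in the window; it is refined
by a parabola through the logarithms of the top three samples, which is
exact for a Gaussian on a locally uniform grid whatever the grid phase (a
plain parabola is the fallback when a neighbour is non-positive). The
centroid is the intensity-weighted mean of the contiguous points above half
height; widths at 10/25/50/75% height come from linear interpolation of the
outward crossings (monotone by construction). Tail areas are trapezoid
integrals between the 10% and 50% crossings on each side; symmetry is the
right-half over left-half area between the 10% crossings; goodness-of-fit
is the R² of a least-squares Gaussian over the 10%-crossing span, clipped
to [0, 1]. "Subsequent peaks" (detector ringing) are local maxima within
1 Th to the right of the apex with height ≥ 1% of it, nearest first.

Detection requires the apex to exceed the local baseline median plus 3 MADs
(baseline taken from ±0.5 Th with the central ±0.12 Th excluded). A missing
peak yields a fixed-length sentinel fit: zero intensity, widths and areas,
worst-case mass error (the search tolerance), zero goodness-of-fit — the
vector length never varies. Local SNR is capped at 10⁶ so noiseless input
cannot inject infinities into the vector.

Mass windows summarize everything outside the expected peaks: per window,
the local-maxima count above a median+3·MAD threshold, the intensity sum,
intensity percentiles computed after removing ±0.1 Th exclusion zones
around expected ions (so a drifting QC peak cannot masquerade as dirt), the
ten tallest maxima (zero-padded) and percentiles of that top-10 list.

The default schema reproduces the counts stated in the README exactly
(2,850 = 1,720 + 720 + 140 + 180 + 90). The per-peak quantity list (23),
the window quantity sets (24/20/18) and the lock-mass descriptor set (70 =
23 base + 9 extra width fractions + 10 ringing terms + 28 neighbourhood
percentiles) are configuration with these defaults; only the totals and
the window widths (50/100/200 amu) are treated as fixed design anchors.
Feature names follow `provenance:peak_or_window:quantity:stat` and the
vector order is deterministic (provenance block, then m/z, then quantity,
then statistic).

## Quality indicators

Sixteen indicators condense the vector; each has a direction (is a high
value good or bad news?). Resolution at the 200 and 700 Th anchors is
theoretical m/z over the fitted FWHM of the nearest monoisotopic peak.
Average accuracy is the mean |ppm| over found QC peaks. `chemical_dirt` and
`instrument_noise` are the total background-scan and flow-stop-scan
intensities; `signal` the summed monoisotopic heights; `s2b` and `s2n` the
corresponding ratios (capped at 10⁹ when the denominator vanishes);
`transmission` the mean high-mass (≥ 450 Th) over mean low-mass
monoisotopic height. Isotopic presence is the fraction of isotopologues
found; isotopic accuracy is one minus the mean isotope-pattern deviation
(mean absolute difference between observed and theoretical relative
abundances per compound). `fragmentation_305` and `fragmentation_hi` are
fragment-to-parent height ratios for fluconazole and the highest-mass
analyte; `baseline_25_150` / `baseline_50_650` are the 25th/50th
exclusion-filtered intensity percentiles of the 50-amu windows containing
m/z 150 and 650. The roster beyond the mandatory names, the anchors, and
every formula are configurable; the count of 16 is the design anchor.

## Outlier detection

Both detectors classify each indicator univariately and one-sidedly:
`higher_better` indicators can only be flagged low, `lower_better` only
high, so a suspiciously *good* value never costs score points.

The quantile detector derives a static acceptance bound from the 5th/95th
historical percentile once ≥ 60 runs are stored; it assumes a stationary
instrument. The isolation-forest detector (the default) refits a univariate
forest (100 trees, subsample ≤ 256, contamination 0.05, seeded) over
history + new run on every arrival, re-evaluating the whole stored history,
and therefore adapts to slow drift; it activates at ≥ 20 runs. Two
small-history compensations apply: an indicator whose historical SD is
below machine epsilon is never flagged, and at most ⌈n/10⌉ runs may be
flagged per indicator (the most anomalous are kept). The run score is the
number of non-outlier indicators; more than 4 outliers marks the run bad;
if the active method cannot run, the run stays unscored.

## Trend detection

Indicators are screened by OLS on calendar time (not run index — cadence is
irregular) over trailing windows of 14, 30 and 60 days, with at least 8
runs per window. A trend is called when R² ≥ 0.40 **and** the fitted line
moves by ≥ 10% of its starting value across the window. The R² threshold
was chosen so that (i) pure-noise windows fire in well under 5% of cases
for n ≥ 8 (the null R² distribution at these n puts < 1% of mass above
0.40 for n ≥ 14), and (ii) a linear drift whose noise SD is up to a quarter
of the total change over the window — population R² ≈ 0.57 — is still
detected with ≥ 90% probability at daily cadence. A stricter threshold such
as 0.65 would sit *above* that population R² and miss a majority of such
drifts; the relative-change gate is what keeps statistically clean but
analytically irrelevant slopes out of the report.

## Association analysis

`correlate_settings` reports per-setting Pearson r against one indicator
with Bonferroni adjustment over the number of settings tested (constant
settings are excluded as undefined). `compare_groups` splits runs at the
indicator's 80th percentile and compares every setting across groups with
Kolmogorov–Smirnov, Mann–Whitney U and Kruskal–Wallis tests; each test
family is Benjamini–Hochberg adjusted across settings, a setting is called
significant only when **all three** adjusted p-values pass (the most
conservative consistent rule), the reported p is the largest of the three,
and the sign is that of the median difference (blank when medians are
equal, as with a pure variance change).

`pc_causal_graph` implements the PC algorithm for continuous data:
PC-stable skeleton search with Fisher-z partial-correlation tests
(conditioning sets grown from adjacency, capped at size 3 for tractability
at pilot-scale n), v-structure orientation from separating sets, Meek rules
iterated to closure, conflicts left undirected and orientation guarded
against directed cycles — the output is a CPDAG. The working significance
level is 0.15; note that with so liberal an α the skeleton retains a false
edge per ~25 absent pairs on null data, which is the accepted trade-off for
sensitivity at small n. Only tunable settings enter the causal analysis
(readbacks are consequences, not causes, of instrument state); the reduced
view keeps edges incident to at least one indicator.

## Synthetic data

`simulate_acquisition` renders Gaussian profile peaks with FWHM = m/z ÷ R
(default R = 30,000) on a TOF-like grid: locally uniform fine sampling of
FWHM/10 around every expected position (overlapping regions are split at
midpoints so each peak owns a uniform, centre-anchored grid — apexes and
centroids are then unbiased by grid phase), 0.1 Th coarse sampling
elsewhere. It adds a piecewise-constant chemical baseline (60 down to 12
counts across 100-Th regions), five plausible contaminant ions (TFA, fatty
acids, …), decaying ringing echoes (2% and 0.8% at +0.3/+0.6 Th), optional
exponential right-tail contamination, Gaussian shot noise (clipped at
zero), and half-normal detector noise in flow-stop scans. Peak heights
(3×10⁵–1.5×10⁶ counts) and the ~4% indicator-level run-to-run CV of the
history generator are set to what a well-tuned QTOF produces on such a mix.

`simulate_history` draws indicator series around realistic means with
planted anomalies (shifts in SD units), linear drifts over calendar
windows, and ~50 tunable + 10 readback settings with planted linear
settings→indicator links (coefficients in per-SD units). All generators
are bit-reproducible given a seed.

What the generator does **not** emulate: real TOF peak-shape asymmetries
beyond a single exponential tail, mass-dependent resolution laws,
space-charge and detector saturation, correlated drift across indicators,
missing injections, or vendor-specific noise spectra. Passing tests
therefore demonstrate that the *algorithms* recover known truth under
idealized but structurally faithful conditions — not that any specific
real instrument will show the same detection rates.

## Problem sizes and numerical choices

The verification experiments use one full 120-scan acquisition for count
and recovery checks; 50 seeds × 60-run histories for anomaly power; 40
seeds of 60-day daily-cadence series for trend power (noise SD at the
maximal slope·15 days level) and 16-run null windows; 25 seeds of
n = 1000 histories with a 3-settings→3-indicators planted graph (plus
n = 2000 chain/collider oracles) for causal recovery. These sizes give
stable rates while keeping the whole verification run in minutes on one
CPU. Tolerances: resolution/fragment recovery 2% (grid-interpolation
limited), noiseless mass accuracy is exact to floating rounding, quantile
bounds ±0.15 at n = 1000. Tie-breaks: equal-height TIC apexes resolve to
the earliest scan; store orderings break timestamp ties by run_id;
equal-median group comparisons report a blank sign.

## Known limitations

* The registry beyond fluconazole and the lock-mass adduct species are
  provisional defaults, not a published mixture recipe.
* The feature schema's per-peak/per-window quantity lists are one
  consistent realization of the printed family totals; other partitions
  exist.
* Isolation-forest flags depend on the seeded forest; verdicts are
  reproducible only with the stored seed.
* PC output is an equivalence class (CPDAG); edges that Meek rules cannot
  orient remain undirected rather than being guessed.
* No multivariate outlier model across indicators, no changepoint or
  seasonal analysis, no cross-batch harmonization.
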