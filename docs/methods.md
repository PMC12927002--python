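# Methods

`corticomap` implements the computational half of a corticosteroid MSI
(mass spectrometry imaging) study: locating Girard T (GirT)-derivatized
corticosterone, 11-dehydrocorticosterone and aldosterone in mouse kidney
sections, comparing their zonal abundance across dietary salt groups, and
quantifying the same steroids in plasma through weighted calibration curves.
This note records the models, the parameter choices and their rationale, the
numerical conventions, and what the synthetic-data tests do and do not
demonstrate.

## Derivative mass chemistry

GirT condenses with the 3-keto group of Δ4-3-ketosteroids, losing water and
leaving a permanently charged hydrazone; the net composition change is
+C5H12N3 with charge +1. Masses are computed from a fixed monoisotopic
table: ¹²C = 12 (exact), ¹H = 1.0078250319, ²H (written `D`) = 2.0141017780,
¹⁴N = 14.0030740052, ¹⁶O = 15.9949146221 Da, and theoretical m/z subtracts
one electron mass (0.00054857990 Da) per positive charge. This table
reproduces the conventional 4-dp theoretical values for the
11-dehydrocorticosterone and aldosterone derivative cations (458.3013,
474.2962). The corticosterone derivative computes to 460.31698; the 4-dp
figure 460.3169 often quoted for it is the *truncation* of this value, so
`corticomap` keeps full precision internally and displays 460.3170 under its
half-up rounding convention (m/z to 4 dp, Δppm to 2 dp).

Derivative identity is confirmed through the two diagnostic CID neutral
losses of GirT hydrazones — trimethylamine (C3H9N, 59.07350 Da) followed by
CO (27.99491 Da) — predicted as cumulative losses from the precursor and
matched against observed product ions within a ±10 ppm tolerance. CID
product spectra are less well mass-calibrated than MS1, hence the wider
default than the 5 ppm MS1 extraction window.

## Extraction and normalization

imzML I/O is delegated to `pyimzml`. Pixels live on a 0-based integer grid
(x = column left→right, y = row top→bottom); imzML's 1-based scan positions
are converted at the boundary. Written files use float64 m/z *and*
intensity so a write/read round trip is bit-exact; note that an empty peak
list cannot be represented in imzML, so such pixels are dropped (with a
warning) on write. Profile-mode spectra are accepted but flagged; a simple
local-maximum picker (off by default) converts them to centroids.

Targeted extraction sums all centroids within a symmetric ±5 ppm window
around the theoretical m/z (sum, not max, to be robust to split centroids;
both the window and the aggregation are parameters). The default window
reflects FT-ICR-class mass accuracy (~1 ppm) with headroom for calibration
drift.

Normalization is the per-pixel ratio of analyte to internal-standard (IS)
intensity, computed *before* any averaging. MALDI intensity varies across a
section through matrix inhomogeneity and regional ion suppression; because
the deuterated IS is sprayed uniformly with the reagent, these effects are
common-mode within a pixel and cancel in the ratio. Pixels where the IS is
not strictly above a floor (default 0) are undefined rather than zero —
low-IS ratios are unstable, and the floor is exposed for stricter QC.

## Column profiling and zone alignment

A rectangular ROI is drawn from the renal pelvis to the outer cortical edge
and collapsed to a 1-D profile: each profile value is the arithmetic mean of
the defined ratio pixels in one ROI column (an orientation flag selects
which lattice axis is the profile axis, so profiles always read
pelvis→cortex left→right). No minimum pixel count is imposed by default; a
column with no defined pixel is undefined. At the default 75 μm raster the
shipped synthetic ROI (≈2.3 mm²) sits inside the 2–3.5 mm² range typical of
such analyses.

Zones (IM, OM, IC, OC, optionally pelvis) are annotated as contiguous column
intervals per section. Sections differ in size, so each zone's **reference
length** is the maximum column count over the cohort's sections, and shorter
zones are expanded to it by deterministic adjacent-point imputation: the
k = N − n missing points are placed at equally spread fractional positions
p_j = j·(n−1)/(k+1) along the zone, and each takes the mean of its two
flanking original values (a length-1 zone is replicated). Original values
are never altered or reordered, and midpoint insertion preserves
monotonicity and segment extremes.

Two QC thresholds attach to this step. A zone requiring more than 20%
imputed points is flagged non-compliant and excluded from group statistics
(kept, with a warning, for inspection); whether a zone fell below 70% of the
reference length is recorded as an annotation on the compliance report.
These two published thresholds are not mutually consistent as a single rule
— one reading imputes only sections below 70%, the other caps imputation at
20% — so `corticomap` imputes *every* short zone, gates statistics on the
20% cap, and reports the 70% figure as QC metadata, surfacing the ambiguity
instead of hiding it. Zone means include imputed points by default (each is
an average of its neighbours, so the effect on a zone mean is mild); a flag
excludes them.

## Group statistics

Zone means (one value per animal per zone per analyte) and plasma
concentrations are compared by one-way fixed-effects ANOVA followed by
two-sided single-step Dunnett comparisons of each treatment diet against
control. The Dunnett adjusted p is computed from the factor-analytic form of
the equicorrelated multivariate t: with λ_i = √(n_i/(n_i+n₀)) and pooled
scale U (ν U² ~ χ²_ν),

P(max_i |T_i| ≤ t) = E_U E_Y ∏_i [Φ((tU + λ_i Y)/s_i) − Φ((−tU + λ_i Y)/s_i)],

evaluated with 96-node Gauss–Hermite quadrature over Y and adaptive
quadrature over U. The computation is deterministic and accurate well below
1e−6: with one treatment group it agrees with the two-sided pooled t-test to
machine precision, and the test suite also checks it against a 10⁵-draw
Monte-Carlo max-|t| oracle and against an independent library
implementation. The per-animal zone mean is the ANOVA unit (n = 6/group),
matching the design in which sections are biological replicates.

The active:inactive glucocorticoid ratio is corticosterone / 11-DHC per
sample, undefined when the denominator is not positive.

## Plasma calibration

Responses (peak-area ratios of steroid to IS) are regressed on nominal
concentration by weighted least squares with w = 1/x — the bioanalytical
convention that keeps relative error roughly constant across a wide range —
with a free intercept (the solve is delegated to statsmodels WLS). Unknowns
are back-calculated through the curve and flagged `below_range` /
`above_range` against the validated ranges (aldosterone 0.05–2.5,
corticosterone 0.05–250, 11-dehydrocorticosterone 0.10–25 ng/mL) rather than
reported as quantitative. %CV uses the sample (n−1) standard deviation.

## Supervised zone markers

Untargeted ions are pooled across pixels, sorted, and clustered wherever the
gap between consecutive m/z exceeds the bin width (default 10 ppm);
clusters present in ≥5% of pixels become candidates. Each candidate is
scored per zone by the ratio of its mean intensity inside the zone to its
mean over the rest of the labelled tissue (capped at 10⁶ for ions absent
outside). The score is scale-invariant, ~1 for spatially uniform ions, and
ranked per zone with an m/z-ascending tie break. This replaces manual
software triage with a reproducible score; the numeric threshold for calling
an ion a marker is a user decision, and unsupervised clustering is
deliberately out of scope. AUROC against the zone mask would be a natural
alternative score; the mean ratio was chosen for interpretability.

## Synthetic data: what it emulates and what it does not

A synthetic section is a cartoon kidney: concentric elliptical bands
(pelvis, IM, OM, IC, OC; semi-major axes 8/20/30/40/50 px at 75 μm, axis
ratio 0.62, pelvis off-centre) — adequate for 1-D pelvis→cortex profiles,
with no attempt at anatomical realism. Per tissue pixel the centroided
spectrum contains the three analyte derivative ions, the IS ion, and planted
zone-marker ions. The default grid gives ≥500 pixels in every scored zone.

The noise model has three parts, all seeded through a single PRNG stream:

* a smooth low-order-polynomial IS drift field scaled to exactly
  ±30% (a testing choice — realistic MALDI drift magnitudes are not well
  established), emulating matrix inhomogeneity;
* multiplicative log-normal noise with mean 1 and CV 20% per pixel per ion;
* uniform m/z jitter within ±1 ppm (FT-ICR-class accuracy).

Analyte intensities are generated proportional to the *realized* (noisy,
drifted) IS intensity in the same pixel times the true zone ratio and an
independent log-normal factor. Suppression and drift being common-mode
between analyte and IS is precisely the physical assumption that justifies
per-pixel IS normalization; it also keeps zone means unbiased, so parameter
recovery tests compare against the serialized truth directly. Consequently
the drift-cancellation check (ratio-image CV with ±30% drift ≤ 1.2× the
no-drift CV at the same seed) holds by construction here — it validates the
normalization path, not the realism of MALDI physics. With zero noise,
drift and jitter, the entire pipeline is an exact identity on the true
ratios.

Cohorts vary section size by a uniform scale (first section fixed at 1.0, so
the reference section is deterministic) to exercise imputation, apply diet
effects as per-zone per-analyte multipliers (e.g. outer-cortex
corticosterone ×2 under low salt), and add per-animal log-normal
variability (CV 15%) so group comparisons are not degenerate. Plasma panels
use three groups (low/control/high salt, n = 6) with aldosterone means
1.6/0.8/0.2 ng/mL (suppression with rising salt), corticosterone flat at
30 ng/mL, and 11-DHC 5/10/5 ng/mL (lower in both extremes), sample CV 20%;
calibration designs are 11 geometrically spaced levels across each validated
range with 5% response CV.

Passing tests on these data show that the pipeline recovers known spatial
and group structure under realistic noise magnitudes; they cannot show
robustness to features the generator omits — isobaric interferences, isotope
envelopes, chimeric or profile spectra, irregular tissue shapes, staining
deformation, or chromatographic artefacts.

## Problem sizes and numerical conventions

* Parameter-recovery runs use six 112×72 sections (≈4,900 tissue pixels
  each); power studies use 100 seeded runs of scaled sections (axes ×0.75,
  ≈3,500 tissue pixels, width variation 5–7% so all zones stay within the
  20% imputation cap) — sizes chosen to estimate detection rates with
  ~3% Monte-Carlo error.
* Column means accumulate sequentially top-to-bottom (not pairwise), making
  profiles bit-reproducible and independent of vectorisation.
* Marker ranking ties break by ascending m/z; gap-based m/z clustering uses
  the relative gap between consecutive sorted peaks.
* Degenerate inputs are errors, not silent defaults: zero charge, empty
  zones, out-of-bounds ROIs, shrinking imputation targets, calibration with
  <3 distinct levels or non-positive nominals under 1/x weighting.

## Known limitations

* Tissue results are semi-quantitative (ratios to a single IS); no absolute
  tissue concentrations are produced, and only one IS channel is modelled.
* Zone annotation is manual (column intervals); no segmentation of histology
  images.
* The marker score ignores spatial autocorrelation; its p-values are not
  modelled, only ranks.
* Rectangular ROIs only; no free-hand regions or 2-D elastic registration
  across sections.
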