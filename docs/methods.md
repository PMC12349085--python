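# Methods

This note documents the models, conventions and numerical choices behind
`xrfmorph`, and what the synthetic-data tests do and do not demonstrate.

## Spectrum formatting

A µXRF export is a sequence of (energy, mean counts per pixel) points whose
energy registration varies slightly (±20–25 eV) between samples, so the raw
points are not homologous across spectra. The formatting chain makes them
comparable:

* **Continuous reconstruction** — linear interpolation between exported
  points. Linear is the simplest shape-preserving choice; splines would
  smooth peak summits and invent curvature between sparse points.
* **Energy window 1.7–18.3 keV** — outside the P K-edge … U L₃-edge range the
  detectors' optimisation makes the signal unreliable. Window endpoints are
  synthesised by interpolation so every spectrum has identical support.
* **log₁₀(counts + 1)** — fluorescence peak heights span orders of magnitude;
  the log makes trace-element peaks commensurable with matrix peaks. The +1
  offset keeps zero-count channels defined, is exact in the limit of large
  counts, and preserves ordering. The raw data are mean counts per pixel and
  may be fractional.
* **Standardisation** — each spectrum is z-scored (mean 0, *population* sd 1
  over its subset channels). Divide-by-n is a convention choice; the paper
  trail of downstream results is invariant to it up to a constant factor.
  Standardisation happens on the subset channel representation *before*
  landmark sampling; landmark vectors are samples of the standardised curve
  and are not re-standardised.
* **Landmarks** — the standardised curve is sampled at 1.7 + 0.02k keV,
  k = 0…830, i.e. 831 fixed energies. The fixed grid is assumed to absorb
  the residual ±25 eV registration jitter, which is well inside the detector
  resolution (>120 eV FWHM at Mn Kα₁).

Energy calibration from reference peaks (e.g. Ca Kα₁ 3.692, Fe Kα₁ 6.405,
Y Kα₁ 14.958 keV) is a least-squares affine fit (quadratic term optional with
≥3 references); residuals are reported so miscalibration is visible.

## Session realignment

Different beamline setups distort spectral shape (sensitivity curves,
scatter above ~17.5 keV, offsets). The correction assumes the distortion is
*additive on the standardised landmark scale and shared by all zones of a
session*. For every zone measured in both a session S and the reference
session R (the control specimens), the difference of standardised landmark
vectors is computed; the mean difference Δ_S is subtracted from all rows of
S. Each session is aligned directly to the reference — no chaining, so
errors do not accumulate. Consequences of the algebra:

* aligning the reference session is the identity;
* within-session differences are preserved exactly;
* the mean homologous residual after alignment is exactly zero, and if the
  true offset is constant across zones the residuals vanish identically.

Zones measured in several sessions are then collapsed to their landmark-wise
mean (session label "merged") so multiply-measured specimens do not dominate
the ordination. Control zones are recognised structurally (same zone_id in
more than one session); no manifest flag is needed.

Limitations: a multiplicative sensitivity distortion is only approximately
additive after log-standardisation, so realignment removes the bulk but not
the entirety of a realistic setup effect; the residual is part of the noise
floor in the synthetic end-to-end tests.

## Ordination

Covariance PCA (column centering only). Rows are already standardised
spectra, so per-landmark variance rescaling would re-weight peak-height
information; correlation PCA is deliberately not offered. All min(n−1, p)
components are retained and the explained-variance ratios sum to 1.
Component signs are fixed (largest-magnitude loading entry positive) to make
runs bit-reproducible; pole orientation is otherwise arbitrary. Sub-analyses
(e.g. the sediment-gradient ordination) are the same operation under a row
filter. Component-count presets: 2 for display, 6 for clustering, 21 for the
discriminant model; a cumulative-variance threshold can replace the presets.

## Clustering

* **k-means**: best of 10 k-means++ starts by total within-cluster sum of
  squares (scikit-learn backend). Assumes spherical clusters — on elongated
  gradient-structured data it is expected to fail, and the synthetic suite
  does not require it to succeed.
* **Ward**: Ward.D2 agglomeration on Euclidean distances
  (scipy backend); the dendrogram is cut at the requested count; merge
  heights are monotone.
* **Gaussian mixtures**: in-package EM under four covariance constraints in
  the volume/shape/orientation nomenclature — EII (shared spherical), EEE
  (one shared full covariance), EEV (shared eigenvalues, free per-component
  orientations), VVV (free). These bracket the constraint of interest (EEV)
  between maximally rigid and maximally flexible; the full 14-family taxonomy
  is out of scope. The EEV M-step eigendecomposes each component's weighted
  scatter, pools the sorted eigenvalue spectra across components, and keeps
  per-component eigenvectors — the standard estimator for that constraint.
  Initialisation is k-means hard assignment; several restarts; the EM
  log-likelihood is monitored and must not decrease. BIC is computed as
  2·logL − p·log n with p the family's free-parameter count and *maximised*.
  Degenerate covariances are regularised with 1e-6·I and logged.

Model selection at k = 2 on gradient-structured scores is genuinely
bistable: the mixture can prefer splitting the sediment composition gradient
itself rather than sediment-plus-calcitic-fossils versus other fossils.
Across seeds of the default synthetic scenario the planted-split agreement
ranges ~0.79–1.00. The seeded tests assert the high-agreement regime; the
bistability is a property of two-cluster model selection, not of the EM
implementation.

## Discriminant model and validation

Classical LDA on the leading PCA scores: pooled within-class covariance
(denominator n − C) with a 1e-8 diagonal ridge for numerical stability,
discriminant axes from the generalised eigenproblem Sb·a = λ·Sw·a with the
usual a'·Sw·a = 1 normalisation, priors proportional to class frequencies
(classes are highly unbalanced; proportional is the conventional default).
Posteriors are Gaussian class-conditionals under the pooled covariance.

Classes represented by a single specimen cannot support a discriminant model
and are rejected with a hard error; the pipeline drops them (and refits the
PCA on the reduced matrix) before the final model, which in the emulated
study design takes 228 rows to 225.

LOOCV is reported in two modes: `pca_outside` fits the PCA once on all rows
and refits only the LDA per fold (the conventional protocol, slightly
optimistic because the held-out spectrum influenced the ordination), and
`pca_inside` refits the PCA within every fold (leakage-free). Both numbers
are always written to the run report; on the default synthetic scenario they
differ by well under one percentage point. Inside folds a class may
temporarily shrink to one member; the fold-local fit then permits singletons.

## Attribution

The discriminant model lives in PC space; attribution chains the two
contribution layers back to energies: landmark l's score is
`s_l = Σ_k L²_{lk} · w_k`, where `w_k = Σ_j λ_j a²_{kj}` weights PC k by its
squared scaling on each discriminant axis times that axis' share of the
between-class separation. This combination rule is this package's
formalisation of "contribution of each landmark to each PC × contribution of
each PC to the LDA"; it is exactly invariant to axis order and to sign
conventions. The profile is rescaled to max 1. Contiguous landmark runs
above the (1 − top_fraction) quantile (default top decile) become intervals;
each interval's peak landmark is matched against the bundled emission-line
table within a tolerance of 0.06 keV ≈ half the detector resolution.
Element presence calls should rest on the primary line (Kα₁, or Lα₁ for the
L-series): Kβ₁ lines collide with other elements' Kα₁ (Cr Kβ₁ 5.947 under
Mn Kα₁ 5.899; Rb Kβ₁ 14.961 under Y Kα₁ 14.958), a physical ambiguity of
energy-dispersive XRF, and `reported_elements(..., primary_only=True)`
implements that convention.

With many genuinely differing elements the top decile (83 landmarks) cannot
contain every differing element's Kα₁ neighbourhood — strong peaks and their
Kβ/escape companions exhaust the budget, and squared loadings square the
amplitude hierarchy. Recovery guarantees are therefore stated for
*controlled* datasets in which a known, small element set differs
(`SimulationScenario.flatten_except`); on the rich default scenario the
top-decile intervals recover the strongest half of the differing elements,
which is reported but not gated.

## Synthetic data generator

Per channel of a 0.2–20.6 keV axis (10 eV step), the expected count is

    λ(E) = [bg(E) + Σ_e c_e Σ_lines r·N(E; E_line, σ(E_line)) + escapes + scatter]
           × sens_session(E) × exposure + offset_session(E) × exposure

with σ(E) = FWHM(E)/2.355, FWHM(E) = 0.05 + 0.033·√E keV (≈130 eV at Mn Kα₁,
a realistic silicon-drift-detector resolution), Kβ/Kα ratio 0.135, Lα only
for the L-series, no lines above the 18 keV excitation energy, Si escape
peaks at E_line − 1.742 keV with fraction 0.02 (producing the observed
1.95/2.27 keV features from the Ca lines), an exponential-plus-constant
continuum, a Gaussian scatter feature at 17.8 keV, and Poisson sampling of
the final expectation. Per-sample energy registration jitter is uniform in
±0.025 keV. Concentrations are in arbitrary fluorescence-yield-scaled peak
area units; exposure (default 80) sets the count scale.

The default scenario reproduces the emulated study design: 38 specimens in 8
high-level clades across 7 sites (the clade × site layout of the studied
assemblage), 6 zones each (3 fossil, 3 sediment), one echinoderm and one
arthropod from the best-sampled site measured in all 3 sessions (252 spectra
total). Sediments sit at a specimen-specific position g ∈ U(0, 1) on a
calcitic→ferruginous gradient: Ca and its substituent Sr decrease with g
while Fe and its correlated traces (Zn, Ga, As, Rb, Y) increase. Fossil
zones blend the specimen's clade profile with the local sediment (blend
fraction 0.15 for robust calcitic echinoderms up to 0.5 for thin sponges;
0.85 for poorly preserved ammonoid molds). Element profiles follow the
qualitative structure reported for this assemblage: echinoderms Ca/Sr-rich;
the phosphatic clades share a strong P signal and differ in trace mixes (K,
Ti, Mn, Ni, Co, Zn, Rb, Y and the REE/actinide set Ce, Nd, Th); Cr, Cu, Ge,
Se, Br and Kr are held exactly equal everywhere as the non-discriminant
control. Between-specimen concentration noise is lognormal with CV 0.18,
within-specimen (zone) noise CV 0.08, and per-(site, element) perturbations
CV 0.05 — site effects deliberately an order of magnitude below clade
effects, matching the observed absence of site structure. Sessions differ by
scatter amplitude, additive offset, ±10–12 % sensitivity tilts and local
sensitivity bumps.

Everything is drawn from one `numpy` generator seeded by the scenario seed;
datasets are reproducible bit-for-bit across processes.

What the generator does **not** emulate: detector pile-up and sum peaks,
self-absorption and matrix effects, spatially correlated heterogeneity
within a zone, diffraction artefacts, and non-Gaussian line shapes. Passing
tests therefore demonstrate that the pipeline recovers structure of the kind
assumed — additive session effects, clade-specific mean profiles, a
monotone sediment gradient — not that real beamline data meet those
assumptions.

## Problem sizes and tolerances

The test suite and the acceptance script run the full 252-spectrum design
(the study's own scale); a reduced 8-specimen scenario backs the cheap
end-to-end tests. EM convergence: relative log-likelihood tolerance 1e-7,
max 500 iterations, 5 restarts. LDA ridge 1e-8; GMM degeneracy
regularisation 1e-6. Standardisation and realignment identities are asserted
at 1e-12; oracle equivalences (eigendecomposition, Fisher direction,
analytic single-Gaussian BIC, hand-computed Ward dendrogram) at relative
1e-5 or tighter.

## Known limitations

* The Δ-subtraction corrects only session effects shared across zones; a
  specimen-specific setup interaction would survive it.
* `classify_unknown` assumes the unknown spectrum was acquired comparably to
  the run's reference session — a new setup cannot be realigned without its
  own control measurements.
* LDA on 21 PCs with 8 classes and ~225 spectra is workable but not
  generous; the leakage-free LOOCV variant is the honest headline number.
* Element assignment is nearest-line matching within the detector
  resolution; it proposes candidates and cannot resolve true coincidences
  (Y Kα₁ / Rb Kβ₁).
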