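# Methods

This note records the scientific and numerical choices behind `florahex`:
what is modelled, which conventions were fixed where the field leaves them
open, what the synthetic generator does and does not emulate, and the known
limitations.

## Vision model

The colour model is the noise-free trichromatic hexagon: raw quantum catches
are trapezoid integrals of stimulus × sensitivity × illuminant on a common
wavelength grid (default 300–700 nm at 1 nm — the bee-visible band; receptor
sensitivity is essentially zero outside it, so wider instrument ranges are
truncated on read). Catches are von-Kries-adapted to the background (each
receptor's catch divided by its background catch) and passed through the
saturating transduction E = P/(P+1), so the adapting background excites every
receptor to exactly 0.5 and maps to the hexagon origin. The projection
x = (√3/2)(E_G − E_UV), y = E_B − (E_UV + E_G)/2 sends pure-receptor triples
to unit-radius vertices. There is no receptor-noise term anywhere: the
hexagon model is noise-free by construction, and no discrimination
thresholds are implied.

**Receptor sensitivities.** Measured bumblebee sensitivities are not
packaged; instead a parametric A1 visual-pigment nomogram (Govardovskii-type
alpha band, optional beta band off by default) supplies UV/blue/green curves
with default peaks at 328/428/536 nm, overridable per analysis
(`lambda_max`). Users with measured curves can pass them as `Spectrum`
objects. The illuminant is the CIE D65 table (normalised to 100 at 560 nm);
the background is a documented parametric green-leaf curve
(0.05 + 0.22·exp(−(λ−550)²/2·40²) + 0.30·sigmoid((λ−710)/20)) — a stand-in
for a measured leaf standard, not a claim to match any particular leaf.

**Hexagon orientation.** Hue angles depend on the (arbitrary) orientation of
the hexagon axes; pairwise angular and Euclidean distances do not. The
convention here puts green–UV on x and blue on +y; a `rotation_deg`
parameter rotates the axes, shifting every hue by exactly that angle while
leaving purity, contrast and all distances invariant.

## Spectrum locus and spectral purity

Spectral purity is the radius of a colour locus divided by the radius of the
maximal-saturation boundary along the same hue ray. The boundary is the
spectrum locus — monochromatic lights — closed by the purple line between
its 300 and 700 nm endpoints. Because excitation saturates with intensity, a
monochromatic light's hexagon position depends on how bright it is: dim
lights sit at the origin, and extreme intensities drive *two* receptors to
saturation and migrate toward the hexagon's two-receptor corners. The
packaged convention scales each monochromatic light so its most strongly
excited receptor reaches a fixed adapted catch (`peak_catch`, default 10,
i.e. E ≈ 0.91): bright lights near receptor saturation, reproducing the
familiar rounded-triangle bee spectrum locus that passes close to the
receptor vertices. Under this scaling the locus hue is monotone in
wavelength, the polygon is star-shaped about the origin, and every
monochromatic locus lies on the outer boundary — so each has purity exactly
1 by construction, for any `peak_catch`.

Numerically, the boundary radius is found by ray–segment intersection with
the closed polygon (vertices at 1 nm by default; the step is configurable
since coarser published locus tables exist). Where several crossings occur
the largest radius is taken; loci whose ray meets the purple line get purity
relative to that segment. The exact origin has purity 0 by convention
(maximally unsaturated); purity is clamped into [0, 1] with a logged count —
no clamping occurs for smooth reflectances, which stay well inside the
boundary. Loci within 1e−9 of the origin have undefined hue and are flagged
and excluded from circular statistics.

## Distances

Within each of the six patches, every unordered pair of plants contributes
one record: the Euclidean distance between loci (hexagon units, a proxy for
the chromatic contrast between the two individuals) and the angular distance
between hues (min(|Δ|, 360−|Δ|) ∈ [0, 180]°). n plants give n(n−1)/2
records per patch (435 at n = 30). Plants missing any patch are dropped with
a warning; cross-patch distances are available through the API but enter no
statistic.

## Inferential statistics

**Linear models.** The purity model (purity ~ structure × position, plant
random) and the distance model (√distance ~ structure × position, plant pair
random) are random-intercept models on balanced complete layouts, where they
are exactly equivalent to the randomized-complete-block ANOVA. The module
computes the textbook closed-form sum-of-squares decomposition (block,
structure, position, interaction, residual) and refuses unbalanced layouts
rather than silently approximating REML output — under imbalance the
equivalence breaks and a proper mixed-model fit is the right tool. The
closed form is exact (it matches both a statsmodels OLS decomposition and an
explicit design-matrix projection oracle in the tests) and fast enough for
the 200-replicate Monte-Carlo suites. The √ transform of distances
stabilises the right-skewed distance distribution; back-transformed
(squared) patch means are reported for plotting on the original scale.

**Pairwise comparisons.** All 15 patch pairs get paired (within-plant) t
tests with Benjamini–Hochberg step-up adjustment at q = 0.05 (via
statsmodels); pairs with zero within-plant difference variance are flagged
and excluded from the adjustment. A compact-letter display (insert-and-
absorb) summarises the rejections.

**Circular statistics.** Hue enters in degrees at every interface and
radians internally. The one-way comparison is the Watson–Williams F with the
standard high-concentration correction K = 1 + 3/(8κ̂), κ̂ from Fisher's
approximation to the pooled resultant length; the test warns below κ̂ = 1,
where the approximation is unreliable, and refuses groups whose mean
direction is undefined. Post hoc homogeneity uses Watson's two-sample U²
with a seeded random-permutation null (default 10000 permutations) rather
than critical-value tables, because printed tables do not resolve the
conservative 0.001 level used for these comparisons; rejection is flagged at
that level. Which circular one-way ANOVA variant is "the" standard is
genuinely open; Watson–Williams was chosen as the most widely implemented
and is documented as such.

## Covariance-ratio modularity test

Variables are the 18 patch × receptor excitations, z-scored per column
(ddof 1), so the covariance matrix is the correlation matrix and CR is
invariant to positive rescaling of any variable. "Normalised excitations"
could also be read as a per-flower simplex normalisation; the z-score
reading was chosen as the standard variable standardisation and the
alternative is noted here rather than implemented.

The permutation unit is the individual variable: the 18 variables are
randomly reassigned to modules with sizes preserved (12/3/3 under the
default three-module hypothesis). Permuting whole patches instead would
admit only 6!/(4!·1!·1!) = 30 distinct assignments — too few to resolve
small p-values — so variable-level permutation is the default and the
meaningful choice; the p-value is (1 + #{CR_perm ≤ CR_obs})/(n_perm + 1),
the add-one convention avoiding p = 0 and counting ties conservatively.

The 95% CI is a nonparametric bootstrap over plants (rows), 2.5%/97.5%
quantiles of CR across resamples (default 1000; degenerate resamples are
redrawn up to 10 times). Bootstrap CR is mildly upward-skewed — duplicated
rows inflate apparent within-module covariance — so the interval need not be
centred on the point estimate.

## Synthetic data generator

The generator emulates a Cattleya-like orchid measured at six patches on one
flower of each of 30 plants (180 spectra), the design of the analysis it
supports. Templates are smooth parametric reflectances: pink patches
(sepals, petals, labellum tip) = low pedestal + Gaussian blue band
(~445 nm) + sigmoidal long-wavelength rise; the labellum tip's band is
stronger and shifted toward the UV-blue (highest purity); the labellum base
is a yellow UV-absorbing patch (reflectance < 0.10 below 400 nm, sigmoidal
rise near 484 nm into a green+red plateau). Template parameters were chosen
so that, through the default viewing context, sepals/petals land in the
hexagon's blue sector at purity ~0.28–0.33 (petal base lowest), the labellum
tip in the UV-blue sector at ~0.60, and the labellum base in the blue-green
sector at ~0.43 — the qualitative configuration the analysis expects of this
flower type.

Among-individual structure:

* **module factors** — one latent N(0, 1) factor per module per plant
  (modules: {sepals+petals}, {labellum tip}, {labellum base}) scales the
  chromatic band amplitudes of its patches with SD `module_factor_sd`
  (default 0.20), a mechanistic stand-in for coordinated pigment
  accumulation;
* **patch noise** — an independent amplitude perturbation per patch per
  plant, SD `patch_noise_sd` (default 0.10, half the factor SD);
* **hue jitter** — a per-patch wavelength shift of the chromatic bands,
  SD in nm per patch (default 6 for sepals/petals, 4 for the labellum tip,
  1.5 for the labellum base, making the base the hue-stablest patch);
* **channel noise and measurement noise** — small per-receptor spectral
  perturbations (SD 0.008) and iid per-wavelength instrument noise
  (SD 0.003). Reflectance is clipped into [0, 1] with a logged count.

The **null generator** produces matched non-modular data whose 18 excitation
columns are designed to be independent: no shared factors, no coherent
amplitude noise, and per-patch perturbations built from three spectrally
localised profiles (bumps at 340/425/575 nm), one per receptor channel, with
independent N(0, 0.035) amplitudes. Raw Gaussian bumps leak between
receptor classes where the nomograms overlap (mostly 425 nm into the green
receptor's short-wavelength limb), so the profiles are orthogonalised
through the adapted-catch response matrix of the default viewing context:
at the linear level each profile changes exactly one receptor's catch. This
is the reference condition for the type-I-error suites; residual
correlations at the population level are below 0.05, and the small remaining
size elevation at n = 30 traces to clipping truncation of the darkest
template regions.

**What the generator does not emulate:** instrument noise structure
(wavelength-correlated drift, specular artifacts), within-flower spatial
heterogeneity, real pigment chemistry (amplitudes are phenomenological, not
absorbance models), plant relatedness, and any attempt to reproduce the
printed statistics of real flowers. Passing tests therefore demonstrate that
the pipeline recovers structure *of the kind assumed*, at realistic effect
sizes — not that any particular real dataset would yield the same numbers.

## Monte-Carlo suites and problem sizes

The calibration module measures the size and power of the package's tests by
simulation: CR type-I error on 200 null-generator datasets and CR power on
200 modular datasets (n = 30 plants, 500 permutations each); Watson–Williams
and Watson U² size on 500 von Mises replicates (κ = 20, n = 30 per group);
blocked-ANOVA power against a +3-within-plant-SD labellum-tip shift on 200
replicates. These sizes give binomial 95% bands of a few percent around the
nominal rates while keeping the full suite inside half a minute on one core.

## Reproducibility

Every stochastic procedure (permutation nulls, bootstrap, generator,
pipeline) takes an explicit seed or Generator; the pipeline derives all
stage seeds from one root generator, so a config + seed pair reproduces
every output byte-identically. The run log records the package version,
seed and full configuration.

## Known limitations

* The hexagon is used as a geometry, not a discrimination model: equal
  Euclidean distances need not correspond to equal discriminability for
  real bees, and no receptor-noise-limited alternative is provided.
* The nomogram and leaf background are parametric stand-ins; absolute
  purity values shift slightly with measured sensitivities or backgrounds
  (relative patterns are robust in the tests).
* Circular ANOVA admits no interaction terms, so hue is analysed per patch
  only — a limitation of the method family, not of the implementation.
* The blocked ANOVA deliberately refuses unbalanced data; incomplete plants
  must be dropped (the distance and modularity modules do this with logged
  warnings).
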