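# Methods

## The reference-space model

`traitspace` positions plant entities (individuals, populations, species or
community means) in a phenotypic space defined by up to six traits: adult
plant height H (m), stem specific density SSD (mg/mm³), leaf area LA (mm²),
leaf mass per area LMA (g/m²), leaf nitrogen per unit mass Nmass (mg/g) and
seed dry mass SM (mg). Trait values vary over orders of magnitude and are
approximately log-normal, so each trait is log10-transformed, then centered
and scaled:

    z_t = (log10(v_t) − m_t) / s_t

where m_t and s_t are the mean and standard deviation (n−1 divisor) of the
log10 values over the *reference* rows used to fit the space — not over the
user's own sample. Global centering and scaling is the core design choice: a
user dataset spanning a narrow slice of worldwide trait variation is not
inflated to fill the plane, and trait covariances come from the large
reference sample rather than from a possibly tiny upload.

The space itself is a PCA of the standardized reference matrix, restricted to
any subset of at least two traits and any subset of growth forms (a new PCA
is fitted per subset). Loadings are the eigenvectors of the (n−1)-divisor
covariance matrix, computed via SVD of the centered z-matrix; eigenvalues are
squared singular values over n−1. Because every column has unit variance, the
eigenvalues sum exactly to the number of traits p, and the explained
proportions to 1.

User entities are projected as **supplementary (inactive) individuals**:
standardized with the reference m_t, s_t and multiplied by the reference
loadings. The background plane is never refitted, and a reference row
projected this way reproduces its active score exactly — the package's key
correctness property, asserted to 1e−10 in the tests.

### Numerical conventions

- **Log base.** Base 10. The choice is cosmetic: z-scoring absorbs any
  positive base, so scores are base-invariant (asserted in tests).
- **Divisors.** n−1 for standard deviations and covariances, consistently.
- **Component signs.** For each component the trait with the largest absolute
  loading is made positive; ties broken by canonical trait order
  (H, SSD, LA, LMA, Nmass, SM). Ties are detected within a 1e−9 relative
  tolerance because with exactly two traits the loadings are identically
  ±1/√2 and an exact-argmax rule would let floating-point noise in the
  decomposition routine pick the anchor row.
- **Complete cases.** Rows missing any selected trait (or with a nonpositive
  value, whose log is undefined) are dropped from fitting; in uploads they are
  excluded with a per-entity reason. No imputation or gap-filling of any kind
  is performed.
- **Out-of-range uploads.** Entities whose standardized value exceeds ±4
  reference SDs are projected with a warning, never excluded.

## Density areas and highest-density regions

The occurrence-probability layer over a score plane is a Gaussian
product-kernel density estimate with per-axis Scott bandwidths
h_i = σ̂_i · n^(−1/6), evaluated on a regular 200×200 grid padded by 3
bandwidths on each side (so effectively all kernel mass lies on the grid; the
Riemann sum of the estimate is within 0.02 of 1, asserted in tests). The
product kernel is separable, so grid evaluation is two 1-D kernel matrices
and one matrix product.

A highest-density region at probability mass q is the smallest superlevel
set of the density containing mass q. The threshold is found by sorting grid
cells by density and accumulating cell mass until q of the total is enclosed;
contours at that level are traced with marching squares and mapped back to
score coordinates. Default masses are 0.50 and 0.95, drawn per growth form
when requested; forms with fewer than 10 reference points are skipped with a
warning. Region masses are grid Riemann sums, not polygon integrals — simple
and resolution-controlled; grid size, padding and bandwidths are all
configurable. The density gradient is colored by density (white → red); a
log-density toggle exists for visual tuning only.

Expected accuracy: on a 10,000-point standard bivariate normal sample the
0.95 threshold implies a squared Mahalanobis radius within 10% of the exact
2·ln 20 ≈ 5.99, and empirical coverages of the 0.50/0.95 regions are within
±0.03 of nominal (slight over-coverage, ≈0.516/0.957, is the expected bias of
kernel smoothing: the estimated density is flatter than the truth, so
superlevel sets at a given mass are slightly too large).

## The synthetic reference generator

The worldwide reference dataset (2,214 species, six traits, growth forms) is
not publicly deposited, so the package ships a calibrated synthetic stand-in
that emulates its statistical structure; it is first-class, tested code.

Per entity, two independent standard-normal latent factors are drawn — S
(whole-plant size) and E (leaf economics) — and each standardized log-trait is

    x_t = a_t·S + b_t·E + ε_t,   ε_t ~ N(0, 1 − a_t² − b_t²),

so every x_t has unit variance. Default loadings (a_t, b_t): H (0.95, 0),
SM (0.90, 0.10), LA (0.80, 0.30), SSD (0.60, −0.35), LMA (0, 0.90),
Nmass (0, −0.90). Size traits load on S; the two leaf-economics traits load
on E with opposite signs, encoding the quick-to-slow return trade-off
(high Nmass with low LMA and vice versa). x_t is clipped at ±4 SD and mapped
affinely onto the trait's worldwide log10 range, making those ranges hard
bounds; then exponentiated base 10. Growth form follows the size factor
(S > 1 → tree, 0.3 < S ≤ 1 → shrub, else herb), then each entity is
independently relabelled "other" with probability 0.05. One master seed
derives separate streams for factors, trait noise and relabelling, so the
output is bit-reproducible and adding traits cannot perturb the factors.

Worldwide log10 ranges used (from the published natural-unit ranges):
H [−3, 1.954], SSD [−1.222, 0.143], LA [−0.102, 6.446], LMA [0.690, 3.178],
Nmass [0.394, 1.839], SM [−3.523, 6.312]. The printed upper bound of SM
appears with a typeset-mangled exponent ("2.05 × 10" plus a footnote marker);
it is read here as 2.05 × 10⁶ mg, consistent with the heaviest known seeds
(the double coconut, ≈ 2 × 10⁷ mg fresh; ≈ 10⁶ mg order dry). This reading is
confined to the generator's calibration table.

With these defaults a six-trait PCA of the synthetic table concentrates
~83% of total variance in its first two components, reproducing the
"three-quarters in two dimensions" structure of the real global spectrum.

**What the generator does not emulate:** species identities and phylogenetic
structure, the exact trait covariances and skewness of the real data,
growth-form-specific trait distributions beyond the size link, and any
geographic or sampling structure. Tests passing on synthetic data therefore
validate the *machinery* (standardization, projection, densities, I/O), not
ecological conclusions about real floras.

## File formats

- **Entity CSV.** Canonical trait headings matched exactly and
  case-sensitively (`Nmass` in plain ASCII); values in natural units, no prior
  transformation; configurable separator/decimal/missing marker (separator ≠
  decimal enforced); all other columns carried verbatim. Numbers are written
  with 15 significant digits.
- **Coordinates CSV.** Two `#`-prefixed metadata lines (trait list; number of
  reference entities used to fit the PCA), then the uploaded table in its
  original column order with `PC1…PCp` appended; excluded entities keep their
  row with missing coordinate cells.
- **Space archive.** JSON with a `format: traitspace-archive-v1` tag holding
  traits, growth forms, reference stats (means, SDs, n), loadings,
  eigenvalues, explained proportions, reference scores, and aligned entity
  ids/growth forms — everything needed to project and plot without refitting.

## Figures

The biplot draws reference scores on a chosen component pair (default 1, 2),
the density gradient, optional per-form HDR contours, and the correlation
circle: arrows at loading × √eigenvalue per trait, scaled by s = 0.8 × the
maximum absolute displayed score (configurable) with a dotted circle of
radius s; arrows reaching the circle mark traits well represented on the
plane. Axis labels report the component index and explained variance to one
decimal. Trait boxplots show, per trait on a log axis, the reference
distribution next to one box per projected group (boxes at quartiles,
whiskers at the full range). Export formats are png (with dpi), pdf and svg;
default size 180×180 mm at 300 dpi.

## Known limitations

- HDR contours are grid-resolution-limited; very small regions (tiny n or
  mass) can be coarse at the default 200×200 grid.
- The coverage guarantee of HDRs is asymptotic in n and degrades below a few
  hundred points per subset.
- Reference tables are assumed to fit in memory; no out-of-core path.
- Quantitative grouping columns read from CSV are strings unless converted;
  the CLI converts a fully numeric group column automatically, the library
  leaves extra columns verbatim.
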