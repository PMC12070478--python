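# Methods

## The acuity model

Resolution of a compound eye is limited by the interommatidial angle α, the
angular spacing of adjacent ommatidia. A stimulus of linear size *R* is
treated as resolvable whenever it subtends at least α, giving the resolvable
distance

    D = (R / 2) / tan(α / 2)

and its inversions R = 2·D·tan(α/2) and α = 2·atan(R/(2D)). The relation is
used exactly as stated: a single interommatidial angle defines the limit and
no Nyquist factor (one cycle per two ommatidia) is applied, because the
published design tables for western flower thrips (WFT) verify against the
plain relation. Anatomical acuity is an upper bound — lighting, motion and
contrast can only degrade it — so resolvable here means "anatomically
resolvable at best".

*R* is interpreted as the element's **maximal linear extent** (the diameter
of the flower's circumscribed circle); the source tables do not state the
size convention and this is the one their numbers are consistent with.

The bundled `WFT` receiver uses α ∈ [10°, 14°] (from 60–70 ommatidia per
eye) with the **coarse 14° bound as the design angle**: an element sized at
14° is resolvable at the target distance for every eye in the interval.
Photoreceptor peaks are 363, 476 and 535 nm. Angles are degrees and lengths
centimetres throughout the public interface; printed-table comparisons in
the tests use an absolute tolerance of 0.005 cm (the tables print 2
decimals; their rounding convention is unstated).

## Visibility geometry

A trap hung *h* above the canopy, whose pattern is resolvable to slant
distance `d_max`, is resolvable from canopy positions within a horizontal
radius `sqrt(d_max² − h²)` (the visibility cone). The canopy is treated as
a horizontal plane with viewers at canopy level; `d_max == h` counts as
"resolvable only from directly below" (inclusive boundary, mirroring
`is_resolvable`). Occlusion by foliage, trap tilt and flight trajectories
are not modelled.

Two different extents matter, deliberately: the **pattern element** defines
`d_max` for visibility cones, while the **whole-card diagonal** defines the
choice/no-choice classification of a multi-trap layout — a layout is
no-choice when even the finest assumed eye cannot resolve a whole
neighbouring card at the trap spacing (r_min at the spacing exceeds the
diagonal; equality counts as choice). Whether neighbouring-*pattern*
resolvability would be the better criterion is undecidable from the design
tables; the whole-card convention matches the published 27.5 cm-diagonal
argument, and the returned size range lets users apply the alternative.

## Spectral curves

Photoreceptor sensitivity uses the standard A1 visual-pigment α-band
template with x = λmax/λ:

    S(x) = 1 / (exp(69.7·(a − x)) + exp(28·(0.922 − x))
                + exp(−14.9·(1.104 − x)) + 0.674),
    a = 0.8795 + 0.0459·exp(−(λmax − 300)² / 11940)

peak-normalised so S(λmax) = 1. The β band (0.26·exp(−((λ − λmβ)/b)²) with
λmβ = 189 + 0.315·λmax, b = −40.5 + 0.195·λmax) is available behind
`beta_band=True` and off by default — the α-band-only curves match the
unimodal published overlays, and whether those include a β band is not
stated. Reflectance replicates are linearly interpolated onto a 1 nm grid
over the intersection of their ranges (standard for spectrometer output),
averaged pointwise, clamped at zero with a warning (negative readings are
instrument noise) and max-normalised. Quantum catch / receptor contrast is
deliberately a `NotImplementedError` stub: the toolkit overlays curves but
does no colour-choice modelling.

## The flower element and cover calibration

The source never defines the flower curve, so the element is a parametric
polar rosette

    r(θ) = (R/2)·(c₀ + (1 − c₀)·cos(kθ)),  k = petals (default 6)

whose area is exactly π(R/2)²·(c₀² + (1 − c₀)²/2); the fraction of the
circumscribed circle covered is c₀² + (1 − c₀)²/2. The roundness default
c₀ = 0.9865 is calibrated once from the small-element field card: six
3.68 cm elements on a 12.5 × 24.5 cm card then cover 20.28% — the printed
value — and two 7.37 cm elements give 27.1% against a printed 27.07%. The
printed 28.37% for the single 12.28 cm element is inconsistent with any
fixed shape fraction (it implies ≈0.73 of the circumscribed circle where
the other rows imply ≈0.97); the toolkit reports achieved percentages and
does not treat that column as a validation target. Tests audit areas
against an independent pixel-rasterisation oracle built from the polar
membership inequality.

Element counts for a cover target use round-half-up of
`target·card_area/element_area`, floored at 1. Note the printed 20.28%
sits just below the 6↔2 boundary for the medium element (ratio 1.496); any
target in ≈20.4–21.9% reproduces the published 6/2/1 counts, and 21% is
used in examples.

Layouts enforce the published constraint that the **edge-to-edge gap
between elements exceeds the element size** (each flower independently
resolvable), i.e. centre spacing > 2R. Placement is deterministic:
margin-anchored exact grid factorisations are tried first (1 → centre,
2 → pair along the long axis, 6 → 3×2 grid), with a seeded
rejection-sampling fallback for awkward counts; infeasible packings raise.
Card coordinates are cm from the lower-left corner, y up; SVG export is at
physical scale (1 user unit = 1 mm) with the axis flipped to SVG's
top-left convention. Colours are sRGB stand-ins; no colour management is
applied at render time.

## Capture simulation

The generator emulates the two published experiment designs.

**Lab choice arena.** Per trial, ~50 insects are released at the centre
with one trap of each size class (design distances 5/10/20 cm) at a common
distance; 15 trials per distance. The trap whose design distance matches
the release distance has expectation `mean_matched` (per-distance defaults
2.0/1.7/2.1, the published matched-cell means), the other two
`mean_mismatched` (0.65, mid published mismatched range). Counts are
Poisson; when the joint draw exceeds the released pool it is thinned by a
multivariate hypergeometric draw, so per-trial totals never exceed the pool
(a mild departure from pure Poisson at high means). Setting the
variance-to-mean ratio φ below 1 switches to under-dispersed binomial
counts; a multinomial competition mode (insects choose one trap or none) is
provided, since independent-Poisson-with-cap vs multinomial is not
determinable from aggregate counts.

**Polytunnel (no-choice).** Nine size × height placements (design
distances 15/30/50 cm, heights 15/30/50 cm), one replicate per crop row,
4 rows in each of 3 tunnels (N = 108, n = 12 per placement). The covariate
x is the maximum horizontal range over which the pattern is resolvable
(0 when resolvable only from directly below, or not at all), computed from
the visibility geometry. Counts follow

    log μ = β₀ + β₁x + β₂x² + u_tunnel + u_row

with β₂ = −curvature, β₁ = 2·curvature·peak (defaults put the peak at
26 cm, the published estimate; the curvature 0.0019231 is a free
calibration, as only the peak is reported), β₀ = log 0.85 (unresolvable-
trap mean, within the published 0.5–1.3 range), normal log-scale offsets
(SD 0.2 tunnel, 0.15 row nested in tunnel), gamma–Poisson noise with
Var = φμ (φ = 2) and structural zeros with probability 0.1. All randomness
descends from one seed through spawned per-trial/per-row streams, so
datasets are byte-identical across runs of the same seed and config.

What the generator does **not** emulate: spatial position within rows,
olfactory cues, insect depletion over 48 h, weather, or the single extreme
outlier the field analysis excluded. Passing calibration tests therefore
demonstrates that the *inference pipeline is correct for its stated model*,
not that the model captures every feature of field data.

## Count-model inference

`fit_count_model` is a log-link Poisson regression fitted by IRLS
(convergence flagged, not raised), with the quasi-likelihood correction
Var = φμ: φ is Pearson χ²/df and the coefficient covariance is scaled by
φ, which is valid for both under- and over-dispersion. Empty design cells
are detected and named before fitting. Nested models are compared by
deviance; for quasi fits the scaled statistic (Δdeviance/Δdf)/φ_full is
referred to F(Δdf, df_resid) — the standard quasi-F approximation — and
plain fits use χ². Pairwise Wald contrasts with Bonferroni correction can
be formed from the returned coefficient table; Tukey machinery is out of
scope.

The quadratic-range model regresses counts on x and x² with tunnel and
row-within-tunnel **fixed offsets estimated jointly** — a deliberate,
self-contained simplification of the zero-inflated NB mixed model used on
the real field data. It is validated only against the toolkit's own
generator: structural zeros and log-normal group offsets bias the
intercept, not the curvature, so the peak −β₁/(2β₂) remains recoverable.
The peak's confidence interval is a parametric bootstrap (default 10,000
multivariate-normal draws from the quasi-scaled covariance of (β₁, β₂),
seeded; draws with β₂ ≥ 0 are dropped and counted).

## Numerical and testing choices

Simulation sizes in the calibration tests — 1000 null replicates for test
size, 400 for power, 200 seeds × 4000 bootstrap draws for peak-CI coverage
— give Monte-Carlo standard errors of ~0.007 on a 5% rejection rate and
~0.02 on coverage, small enough to audit the claimed bands while keeping
the default suite under a minute. Rasterisation oracles use 0.02 cm pixels
(0.01 cm for single elements). Degenerate inputs fail loudly: zero or
negative lengths and out-of-range angles raise with the offending argument
named; a zero release pool yields all-zero counts rather than an error.

## Known limitations

- Anatomical acuity only: no contrast sensitivity, diffraction, photon
  noise or motion effects, so predicted ranges are upper bounds.
- The flower geometry is a calibrated reconstruction, not the original
  artwork; the large-element cover percentage is knowingly irreproducible.
- The quadratic-peak analysis uses fixed group offsets, not random
  effects; with many sparse groups its standard errors are approximate.
- The generator's curvature, dispersion, zero-inflation and group-SD
  defaults are realistic choices, not published values.
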