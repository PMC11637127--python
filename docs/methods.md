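# Methods

## Model

The package analyses the bistable Allen–Cahn equation for a microbial
density `M(t, x, y)`,

    M_t − d(M_xx + M_yy) + γM³ − γ(1+σ)M² + γσM = 0,

whose reaction factors exactly as `γM(M−1)(M−σ)`.  The uniform states
are `0`, `σ`, `1`; for `σ ∈ (0,1)` the outer two are stable and `σ` is
unstable, so front solutions connecting them describe the spread or
retreat of a biofilm on a surface.  Parameters: `d` (length²/time,
diffusion), `γ` (1/time, growth), `σ` (dimensionless survival rate in
`[0,1]`).  All three default to symbols; numeric `d ≤ 0` or `γ ≤ 0` is
rejected, numeric `σ` outside `[0,1]` warns but is accepted because the
expansion-method parameter sets determine `σ` from auxiliary constants
and may leave the biological interval.

## Lie symmetry computation

Point vector fields `X = χ¹∂t + χ²∂x + χ³∂y + φ∂M` act on a
second-order jet space with coordinates named by sorted multi-indices
(`M_tx ≡ M_xt`).  The second prolongation uses the standard
total-derivative recursion; mixed second-order jets (`M_tx`, `M_ty`)
that appear in the prolonged coefficients are eliminated on the
solution manifold together with `M_t`, using the spatial total
derivatives of the equation.  Splitting the invariance condition by
monomials in the remaining independent jets yields 21 determining
equations for generic parameters.

**Solving the determining equations.** The unknown infinitesimals are
allowed to depend on all of `(t, x, y, M)`.  They are expanded in a
polynomial basis of total degree 2 (60 coefficients), which converts
the determining equations into a linear system solved over the
rational-function field `Q(d, γ, σ)`.  Two safeguards make this more
than an ansatz guess:

* *degree stabilisation*: the dimension of the solution space is
  recomputed at degree 3 and must not change (it is 4 at both degrees);
* *branch conditions*: Gaussian elimination records every
  parameter-dependent pivot factor assumed nonzero (here `d`, `γ`,
  `σ² − σ + 1`), so special parameter values that could enlarge the
  algebra are surfaced instead of silently divided by.  `σ² − σ + 1`
  has no real roots, so no real parameter choice is excluded.

The result is `χ¹ = C₁, χ² = C₂ − C₄y, χ³ = C₃ + C₄x, φ = 0`: a
4-dimensional algebra spanned by the two space translations, the time
translation and the planar rotation.  The commutator table is computed
exactly and checked for antisymmetry, closure and the Jacobi identity.

## Reductions and provenance

Each reduction object is tagged `faithful` or `as_printed`:

* the travelling chains `M = u(t−y)` and `M = u(t−x)` are faithful and
  reproduce `u' − d u'' + reaction = 0` exactly;
* the steady-state second stage with `r = x² + 2x − 2y + y²` actually
  gives the variable-coefficient equation
  `−d(4(r+2)u'' + 4u') + reaction = 0`; the constant-coefficient form
  `4d u'' − reaction = 0` that the auxiliary-equation method targets is
  therefore stored `as_printed`, and `verify_reduction` reports the
  exact leftover `−4d r u'' − 4d u'' − 4d u'` between the two;
* the rotation chain's printed similarity variables `(y, −x)` are not
  rotation invariants and its reduced equation retains a time
  derivative; its final ODE `u' − 2d u'' + reaction = 0` is, however,
  exactly the faithful plane-wave reduction along `k = (1, 1)`, which is
  how the package exposes it (`r = t − x − y`).  The faithful rotation
  invariants `(t, x² + y²)` are computed and checked but no solver is
  attached to them.

The plane-wave reduction `M = u(t − k·x)` is implemented for arbitrary
nonzero `k`; only `|k|²` enters (rotational invariance), and the front
travels at unit speed toward increasing `k·x` by construction — the
convention every later speed check relies on.

## Expansion methods

Homogeneous balance: under each method's auxiliary relation a
derivative raises the effective degree by one (`ς' ~ ς²`), so `u^(k)`
has degree `N + k` and `u^m` degree `mN`; balancing `u''` against `u³`
gives `N = 1` for every reduced cubic ODE here.  Non-integer or
non-positive balance raises a structured error (e.g. `u''` against
`u⁴`).

The coefficient systems are generated by substituting the truncated
ansatz, eliminating auxiliary derivatives through the defining relation
(for the quartic relation, `ς'` survives linearly and its coefficient
is collected separately), clearing denominators and collecting powers.
They are solved by recursive elimination: pick the equation/unknown
pair minimising (number of unknowns, degree, size), solve it, branch on
all roots, and additionally branch on vanishing leading coefficients so
that no solution branch is lost to a generic division.  Radical
equations are handled by sympy's resultant-based solver; because that
can introduce spurious branches, **every candidate set is verified by
back-substitution** into its generating system using a three-valued
zero test (below), and only verified branches are reported (spurious
and constant branches are counted).  For the quartic method the solved
unknowns are `(a₀, a₁, γ, σ)` with `(d, b₁, b₂, b₃)` free; for the
ratio expansion `(a₀, a₁, d, τ)` with `(γ, σ, κ)` free; for the tanh
method `(a₀, a₁, b₁, κ, γ)` with `(d, σ)` free — matching how the
reference tables parameterise their sets.

**Corrected library forms.** The quartic auxiliary relation is used as
`(ς')² = b₁ς² + b₂ς³ + b₃ς⁴` (the unique form consistent with the
16-family solution library and the discriminant `ζ = b₂² − 4b₁b₃`).
Numerical residual checking of the printed library forms found several
typographical slips, which are corrected in the stored forms and
flagged `corrected=True` with the printed text retained: the
`(1 ± tanh)`/`(1 ± coth)` denominators must be squared; the
sech/sec-quotient families need first powers in the numerator; the
csch and csc quotient families must use csch/csc consistently (and the
csch family requires `ζ < 0` for its `√(−ζ)`); the `b₁ = 0` rational
form degenerates to zero as printed and is replaced by
`4b₂/(b₂²r² − 4b₃)`.  All three ratio-expansion case forms fail their
Riccati equation as printed and are stored corrected (prefactor
`−√(κτ)/κ`; a pure tanh/coth ratio with argument `√|κτ|ρ`; third case
`τ = 0, κ ≠ 0` with `H = −A₁/(κ(A₁ρ + B₁))`).  The five tanh-method
case forms are sound as printed.  Every stored form passes the
defining-relation residual check under its validity conditions; the
printed variants remain available for reproducing printed families.

**Reference parameter sets** are carried verbatim with provenance
`paper` and a consistent `±` branch selector.  Their residuals against
the generating systems are computed, never assumed: the steady-state
sets `a₀ = σ` and `a₀ = 0` satisfy their system exactly (the `a₀ = 1`
set only on the `b₂ > 0` half-space, an `|b₂|` branch effect), while
the four travelling sets leave residuals that vanish identically at
`σ = 0`.  The derived counterparts agree with the printed sets in all
coefficients except the recurring factor `σ² + 6σ + 1`, which the exact
computation yields as `(σ − 1)²`; the package carries both and the
σ = 0 concordance is asserted in the test suite.

## Zero testing

Symbolic residuals are decided by a three-valued protocol: canonical
simplification first (skipped above a size threshold, and abandoned if
it inflates the expression); otherwise the expression's top-level terms
are lambdified and sampled at 25 seeded random points, rejecting points
where any term exceeds 10¹⁰ in magnitude (near poles) or where the
stated validity conditions fail.  A point counts as zero when the sum
of terms is below 10⁻¹⁰ of the largest term magnitude.  All-zero →
`zero`, all-nonzero → `nonzero`, otherwise `undecided` (reported, never
silently accepted).  `σ` is sampled on `(0.05, 0.95)` — its biological
range — because several radical identities (`√((σ−1)²) = 1 − σ`) hold
only there; other positive symbols on `(0.1, 2.5)`, signed symbols on
`(−2, 2)`.

## Finite-difference cross-check

`simulate_1d` integrates `M_t = D_eff M_xx − γM(M−1)(M−σ)` by the
method of lines: second-order central differences, mirror-ghost Neumann
boundaries, explicit RK4 with `dt = 0.2 h²/D_eff`.  A norm-growth guard
aborts on instability.  The front check initialises the exact derived
kink (which connects `σ` to `1` and has unit speed in `r = t − x`) on
`x ∈ [−60, 100]` with `h = 0.1` and integrates to `t = 40`; the tracked
level defaults to `(1+σ)/2`, crossing positions are linearly
interpolated and the speed is fitted on the second half of the time
window only.  Measured speeds agree with 1 to better than 0.1% for the
three `(d, σ)` combinations exercised in the tests — this domain size
and horizon give second-order converged fronts well isolated from the
boundaries.  The simulator validations include conservation of the
spatial mean when the reaction is off, pointwise bistable dynamics at
`D_eff = 0` against an independent `scipy` ODE integration, and ≈4×
error reduction per halving of `h`.

## Profile classification

`classify_solution` samples a fully numeric profile on `r ∈ [−10, 10]`
(4001 points).  Poles are detected adaptively (values beyond ~50× the
median magnitude); three or more equally spaced poles → `periodic`;
poles with power-law tails → `rational`; other poles → `singular`.
Bounded profiles: monotone with distinct end levels → `kink`
(increasing in `r`) or `anti-kink` (decreasing); a localized excursion
above/below a common background → `bright`/`dark`; autocorrelation
revival → `periodic`; near-constant → `constant`; otherwise
`unclassified` — ambiguity is reported, not forced into a label.

## Figure presets

The seven presets store the caption parameter values verbatim and the
caption's shape label.  Profiles are evaluated from the *derived*
(exactly verified) sets rather than the printed ones: with the printed
`τ`, the hyperbolic ratio-expansion case places a coth-branch pole
inside the plotting window at the anti-kink figure's parameters, which
contradicts the published smooth picture, whereas the derived `τ`
reproduces it.  Two caption reconciliations are recorded in the preset
notes: the periodic figure cites the `tan` case (valid only for
`κ > 0`) while printing `κ = −1`, so the case-consistent sign is used;
and the bright figures do not fix a `±` branch, so the branch showing
the captioned hump is stored.  Of the seven captions, five are
reproduced (`bright, bright, anti-kink, kink, periodic`); the profiles
cited by the captions labelled `kink` (fig 4) and `dark` (fig 6) are
monotone *decreasing* fronts for every admissible branch — under both
the printed and the derived sets — so those two labels cannot be
reproduced by any faithful evaluation of the cited formulas; the
corresponding acceptance test asserts the caption labels and therefore
fails, by design, on exactly those two.

## Known limitations

* The determining-equation solver uses a polynomial ansatz with degree
  stabilisation; a symmetry with non-polynomial infinitesimals (none is
  expected for this equation class) would be missed.
* Branch conditions are reported but the special-parameter algebras are
  not solved separately.
* `N > 1` truncations and non-classical/contact symmetries are out of
  scope; rotating-frame reductions (`C₄ ≠ 0` combinations) get
  invariants only, no solver support.
* Paper-set audits sample identities numerically when simplification
  stalls; an `undecided` status is possible and is always surfaced.
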