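# Methods

## Model

`trendsvar` analyses K monthly search-interest series (default K = 3:
violent-attack interest VA, gun-control interest GC, gun-purchase
interest GP) with a structural vector autoregression of order one,

    A0 x_t = alpha + mu * t + A1 x_{t-1} + e_t ,

where `x_t` holds the log-scale interest indices in a fixed causal order,
`alpha` is a per-equation level, `mu * t` a linear monthly trend
(t = 1..T), and `e_t` are mutually independent Gaussian structural
innovations with standard deviations `shock_scales`.  Identification is
recursive (Wold ordering): `A0` is unit lower triangular, so each
variable is contemporaneously affected only by variables earlier in the
order.  For K = 3 the free entries of `A0` are `beta21` (VA -> GC),
`beta31` (VA -> GP) and `beta32` (GC -> GP).  With K = 3 the
just-identified model imposes no overidentifying restrictions.

Solving for `x_t` gives the reduced form

    x_t = c + d * t + B x_{t-1} + u_t ,   u_t = L e_t ,  L = A0^{-1} ,

with `c = L alpha`, `d = L mu`, `B = L A1`.  Everywhere in the package
`lag_matrix` stores the reduced-form `B`, the object least squares
estimates directly.  This reading also applies to the reference lag
coefficients in `worked_example`: propagating them as `B` reproduces the
reference variance-decomposition table to within 0.015 at every printed
horizon, whereas the structural reading does not.

## Estimation and identification

- **Reduced form** (`fit.fit_reduced`): equation-by-equation OLS of `x_t`
  on `(1, t, x_{t-1})`.  With identical regressors per equation this is
  the standard asymptotically efficient choice.  The residual covariance
  `Sigma_u` uses denominator `T_eff` (not `T_eff - k`); the O(1/T)
  difference keeps the factorisation/simulation consistency checks exact.
- **Identification** (`fit.identify_structural`): unit-diagonal LDL'
  factorisation `Sigma_u = L Lambda L'` via Cholesky; `A0 = L^{-1}`,
  `shock_scales = sqrt(diag(Lambda))`.  `A0 Sigma_u A0'` is diagonal to
  1e-10 (relative) by construction.  Alternative orderings permute
  `Sigma_u` before factorising; the reduced form is unaffected.
- **Uncertainty** (`fit.bootstrap_fit`): recursive residual bootstrap.
  Centred residual rows are resampled with replacement, panels rebuilt
  from the fitted `(c, d, B)` conditioning on the first observed row,
  and each replicate refitted and re-identified (vectorised across
  replicates).  Standard errors are bootstrap SDs; percentile 2.5/97.5
  bands from the same draws feed the impulse-response fans.  Percentile
  (not studentised) bands were chosen as the common practice for IRF
  fans; one resampling machinery serves both coefficient SEs and bands.
  `n_boot < 100` is rejected because tail quantiles are unstable.

## Shock dynamics

One-standard-deviation impulse responses are `Theta_h = B^h Theta0` with
`Theta0 = L diag(shock_scales)` (unit-shock responses available via a
flag).  The forecast-error variance decomposition at period H uses
`Theta_0 .. Theta_{H-1}`, so period 1 equals the contemporaneous
decomposition and the first-ordered variable's period-1 row is
identically (1, 0, 0) — the defining signature of the recursive scheme.
Shares converge as H grows for stable `B` (below 1e-6 between H = 60 and
H = 120 at the reference parameters).

`dynamics.back_out_shock_scales` inverts period-1 FEVD rows to recover
shock SDs that a published table leaves unprinted, with the first scale
normalised to one.  Because row i of the period-1 decomposition
over-determines a single unknown scale when i > 2, the inversion pools
all cross shares:

    sigma_i^2 = share(i,i) / (1 - share(i,i)) * sum_{j<i} Theta0[i,j]^2 ,

which reduces to `sigma_2 = beta21 * sqrt(share22/share21)` for the
second row.  Rows with no contemporaneous links are unidentified from
shares and default to scale one.  For the reference table this yields
sigma = (1, 1.0032, 0.9925).

## Diagnostics

ADF stationarity tests use constant + trend regression, consistent with
the model's deterministic terms, with MacKinnon p-values (delegated to
statsmodels).  Lag order is scanned by the multivariate AIC
`ln det(Sigma_hat(p)) + 2 m(p) / T_eff` with `m(p) = K(2 + Kp)`, all
orders compared on the common effective sample, ties to the smaller lag.
Only the argmin is comparable across datasets; the AIC level depends on
the data scale and is not a target quantity.

## Synthetic data

`synthetic.simulate_svar` is the generative reading of the model: the
state starts at the deterministic steady level `(I - B)^{-1} c`, a
burn-in of 100 steps (trend frozen at t = 0) removes initialisation
transients, and the retained sample carries trend index 1..T.  Defaults
mirror the study conditions: T = 168 months from 2004-01, reference
point estimates as truth, shock scales backed out of the period-1
decomposition with sigma_1 = 1 (innovation SDs on the log scale are not
separately published; the relative scales are what the decomposition
identifies).  Gaussian shocks match the least-squares estimation and
bootstrap machinery; the innovation law is otherwise unconstrained by
the design.

Event spikes (`inject_event_spikes`) add fixed log-scale magnitudes at
the five attack months that dominate the real series (2012-12, 2013-04,
2015-12, 2016-06, 2017-10), largest in VA, with GC loading hardest on
the first two and GP on the first and third.  Magnitudes (0.2-1.2 log
units) are stylised: they make event months the sample maxima without
overwhelming the autoregressive signal.

`synthetic.simulate_term_sets` derives per-construct search terms as the
construct's latent log series plus iid N(0, 0.15^2) measurement noise,
mapped back through `exp(.) - 1` and the max-100 integer rescale.  The
0.15 log-unit SD produces cross-term correlations around 0.9, similar to
closely related query variants.

**What the generator does not emulate.**  Real Trends extracts add
sampling noise that varies by query date, IP-level deduplication, topic
drift, and composite queries whose union semantics Google does not
document.  The max-100 rescale, integer rounding, term noise and event
spikes are *not* invertible by the log transform, so refitting the
post-processed synthetic data recovers attenuated contemporaneous
coefficients (e.g. beta21 around 0.36 when the latent truth is 0.47 in
the shipped driver output) — a deliberate feature showing the
measurement pipeline's bias, which real-data estimates inherit.
Parameter-recovery checks therefore run on the latent log panel, where
consistency holds; passing them validates the estimator, not the
fidelity of Google's normalisation.

## Ingestion choices

- Composites are the per-month **sum** of jointly-scaled terms, rescaled
  to maximum 100.  Union-query semantics are undocumented; summation
  approximates a union while the rescale matches normalisation on the
  largest term.
- Panel transform is `ln(x + 1)`: Trends series contain zeros, and the
  +1 offset keeps them finite while preserving ranks.
- The censored cell token `"<1"` reads as 0.5, the midpoint of its
  interval (unbiased under a uniform censoring assumption).
- Search-term wording (plurals, word order) is treated as opaque column
  labels; semantics live in the data, not the parser.

## Problem sizes and numerical choices

Consistency and recovery checks use T = 20000 (10 seeds) for point
estimates, T = 1e5 for stationary moments against the discrete Lyapunov
equation, 40000 independent Monte-Carlo replicates for the
path-difference IRF oracle (3-MC-SE agreement bands), and 100 datasets
x 500 bootstrap replicates at T = 300 for interval coverage.  Simulation
rejects lag matrices with spectral radius >= 1; IRF propagation only
warns, since a mildly explosive fitted `B` still has well-defined finite-
horizon responses.  AIC ties break to the smaller lag; table cells round
half-up to two decimals.

## Known limitations

- Results are population-level statements about search interest; the
  model says nothing about individual behaviour, and search interest is
  a proxy for (not a measurement of) attitudes or purchases.
- Recursive identification is an assumption, not a test: the causal
  ordering VA -> GC -> GP is imposed.  Only orderings, not data, can
  change the contemporaneous attribution.
- A single lag and linear trend are maintained hypotheses; the
  diagnostics module checks them but seasonal or longer-memory structure
  is out of scope.
- The composite construction approximates undocumented Trends semantics;
  grid submodels on single terms avoid that approximation entirely.
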