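# Methods

`phytoscreen` analyses dual cell-free / cell-based antioxidant screens of
plant-extract libraries read on 96-well microplates. This note records the
models, the parameters that matter, the synthetic-data design, and the
numerical and design choices, in the order the pipeline runs them.

## Cell-free calibration (TPC, FRAP)

Total phenolic content (Folin–Ciocalteu, 750 nm) and ferric reducing
antioxidant power (TPTZ/Fe³⁺, 593 nm) are calibrated against gallic acid
and Trolox respectively, by ordinary least squares on blank-corrected
standard means:

    A = slope · c + intercept

with a **free intercept**: over the working ranges of both assays the
response is linear, and the intercept absorbs residual blank signal that
survives blank subtraction. Fits with a non-positive slope are rejected
outright (a reducing-power assay must respond positively). `r²` is the
squared Pearson correlation of fitted vs observed. Sample absorbances are
blank-corrected, inverted through the plate's own curve, and rescaled by
the assay dilution factor (`tpc_dilution`, default 17; `frap_dilution`,
default 50 — dimensionless fold dilutions of extract into the reaction).
Sub-blank readings yield negative concentrations, which are **reported
as-is** rather than clipped so that downstream rank statistics remain
unbiased; callers may flag them.

FRAP is read kinetically (every minute until the reaction stops). The
per-well endpoint is the first read after which every consecutive
absorbance change stays below `frap_delta_tol` (default 0.005 AU,
configurable — the assay protocol specifies "no changes in absorption"
without a number). Two deliberate conventions: a trace flat from its
first pair plateaus at the *first* read, and a trace still moving at the
last pair is marked non-converged with the last read used as the best
available endpoint.

## ROS (DCF) kinetics

Each Caco-2 well is read at 0/15/30/60/90 min. Per well:

1. **background correction** — subtract the mean cell-free blank at each
   time point. Blank here means no-cell wells; if a plate carries none,
   the correction is skipped with a warning (the later two-anchor step
   cancels shared offsets only approximately).
2. **start-value normalization** — divide by the corrected t = 0 value.
   The ratio form (not subtraction) makes traces dimensionless, cancels
   well-to-well probe-loading differences exactly, and is what makes the
   anchor identities below hold for any noise realization. Wells whose
   corrected baseline is ≤ 0 cannot be ratio-normalized; they are
   excluded with a logged reason and the exclusion propagates to the
   replicate count (no imputation).
3. **AUC** — trapezoidal integral of the relative trace over the *actual*
   read times (deviations from the nominal schedule are tolerated).
4. **two-anchor normalization** — linear map of the AUC so that the
   plate's AAPH stress-control mean is 100% and its untreated-control
   mean is 0%. Values < 0% and > 100% are legitimate and kept.

Because step 4 is affine in the AUC, the stress-control wells of any
plate average to exactly 100% and the untreated wells to exactly 0% —
this anchor identity is a structural property, not a statistical one, and
the test suite asserts it to 1e-9 under arbitrary noise.

## NO (Griess) normalization

Nitrite absorbance (548 nm) in RAW264.7 supernatants is mapped to
percent of the LPS stress control with the medium-only (DMEM) control as
the zero anchor:

    NO% = 100 · (A − A_blank) / (A_stress − A_blank)

The zero anchor is a design choice: without it, reagent background
inflates every percentage, and the two-anchor form deliberately parallels
the ROS chain. No nitrite standard curve is fitted — the readout is a
percentage, not µM nitrite. A stress mean at or below the blank raises a
degenerate-anchor error (failed induction).

## Viability gate

Resazurin fluorescence is expressed as percent of the untreated-control
mean. An extract whose **triplicate-mean** viability is strictly below
`viability_threshold` (default 80%) is cytotoxic and excluded from the
corresponding cellular endpoint. The gate is per cell line: Caco-2
viability gates the ROS endpoint, RAW264.7 viability the NO endpoint,
and an extract can be excluded from one and retained for the other.
Exactly 80.0% survives ("below" is strict). The gate is a pure
threshold — no accompanying test statistic — and idempotent.

## Hit calling

Each plate's treatments are compared against that plate's stress control
with Dunnett's many-to-one procedure on the replicate normalized
percents. The **family is the plate**: every treatment group sharing a
stress control is corrected together, matching the physical design where
each plate carries its own controls; no library-wide correction is
applied. With pooled one-way-ANOVA variance MSE (df = N − G over all
groups on the plate),

    t_i = (m_i − m_0) / sqrt(MSE · (1/n_i + 1/n_0))

and the adjusted two-sided p-value is P(max_j |T_j| ≥ |t_i|) under the
multivariate-t null with product correlation λ_i λ_j,
λ_i = sqrt(n_i/(n_i+n_0)) (unbalanced designs handled through the
per-group λ). The probability is evaluated by deterministic 2-D
quadrature: conditioning on the shared scale S = χ_df/√df and the common
factor Z₀ reduces the k-dimensional orthant probability to a double
integral, computed with 64-node Gauss–Hermite (Z₀) × 64-node
Gauss–Legendre against the χ density (S); accuracy is ~1e-6, and with a
single treatment group the procedure reduces exactly to the pooled
two-sided t-test. A family whose groups are all constant has no error
estimate and raises a degenerate-variance error.

Calls at `alpha` = 0.05 (two-sided): *decrease* if p < α and mean < 100%,
*increase* if p < α and mean > 100%, else *none*. "Reduced by at least
30%" is a separate flag, mean ≤ 70% on the normalized scale, independent
of significance — the two are reported together but never conflated.

## Selectivity classification

Applied in strict rule order on the normalized means of gated extracts:

1. **excluded** — the viability gate removed an endpoint the rules need;
2. **dual** — NO% < 60 and ROS% < 60;
3. **no_selective** — significant NO decrease and ROS% > 90;
4. **ros_selective** — significant ROS decrease and NO% > 90;
5. **unclassified** otherwise.

The classes partition every gated extract (property-tested). The 60/90
thresholds are implemented as a general classifier, not a top-N report.
Note the rules are intentionally literal: a statistically significant
2-point dip with the other endpoint above 90% earns a "selective" label
— significance and effect size are separate axes.

## Correlations

Spearman rank correlations (mid-ranks for ties; two-sided p from the
t-approximation on n − 2 df) over per-extract means — replicate-level
correlation is out of scope. Pairs are computed on pairwise-complete,
non-excluded extracts, so each pair's n is exactly the number of extracts
passing the gates involved (the NO-vs-ROS n is smaller than either
single-endpoint n). Constant vectors raise an error rather than NaN.

## Synthetic campaign generator

The generator emits complete raw plate files (plate maps + long-format
measurements for all five assays) from a latent ground truth, enabling
end-to-end testing and parameter recovery without any external data.

**Cell-free structure.** A latent phenolic content P is log-normal
across extracts (median `tpc_median` = 500 mg GAE/L, log-sd 0.9 — chosen
so a 375-draw library tops out near the ~8200 mg/L / ~47,000 µmol/L
maxima typical of such screens). TPC ∝ P and FRAP ∝ P^γ (γ = 1,
`frap_per_tpc` = 5.7 µmol TE per mg GAE), each with independent
log-normal assay scatter whose size is solved in closed form from the
target Spearman correlation (default 0.857) via Pearson's relation
ρ = 2 sin(π r_s/6) — the calibration never looks at generated data.

**Cellular structure.** Each extract belongs to one of five latent
classes — inactive, dual, NO-selective, ROS-selective, NO-increasing —
with class-specific offsets for the true normalized levels plus a shared
monotone link to standardized log-P (8 pct/SD for ROS, 12 for NO) and
within-class scatter (SD 10). Offsets, link strengths and the default
frequencies (0.727/0.056/0.075/0.035/0.107) were set by a variance
decomposition so that, in expectation, ≈34/375 extracts sit at
ROS ≤ 70%, ≈57/375 at NO ≤ 70%, ≈40 show NO above 100%, and the TPC–ROS
/ TPC–NO rank correlations land near −0.45. The induced NO–ROS coupling
(~0.35–0.4) is somewhat stronger than the weak coupling (~0.24) such
screens report; a single shared link cannot set all three cross
correlations independently, and the two TPC-facing ones were
prioritized. Cytotoxicity is drawn independently per cell line
(3/375 Caco-2, 15/375 RAW264.7).

**Measurement models.** DCF traces are linear in time,
f(t) = F₀·(1 + R t) with R = r_basal + r_stress·(1 − inhibition), plus a
cell-free background and per-well log-normal loading variation — the
simplest kinetics consistent with an AUC readout. The analysis never
assumes a kinetic form, so this generator/analysis mismatch is
intentional and exercises robustness. FRAP traces approach their plateau
first-order (rate 0.5/min, 16 one-minute reads). Griess absorbance is
blank + span·level. Viability centers healthy extracts at 100% (SD 2%)
and cytotoxic ones at 60% (SD 3%) — a separation regime in which the
gate must recover the truth set exactly. Quercetin positive controls are
emitted at 3.6% residual ROS and 66.5% residual NO, the levels such
screens report for 20 µM quercetin, so the positive-control channel
doubles as a pipeline sanity check. Every well reading carries
multiplicative noise (CV 2% per assay by default); extracts are plated
in triplicate, and every plate carries its own blanks/controls
(cell plates: 3 blanks, 3 untreated, 3 stress, 3 quercetin, 28 extracts;
cell-free plates: 3 blanks, 6 standards × 3, 25 extracts).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: plate-position and edge effects,
evaporation or day/batch drift, probe photobleaching and leakage,
nonlinear calibration ranges, heteroscedastic replicate noise, and
biological replicate variation beyond measurement noise. In particular,
real replicate scatter is larger, so the fraction of extracts flagged
"significant" here (most extracts deviating at all from 100%) is higher
than a real campaign would report; the count-calibrated quantities are
the ≤ 70% filters, not the significance tallies. Determinism: identical
config + seed give byte-identical CSVs (all randomness flows from
`numpy` SeedSequence spawns of the campaign seed).

## Numerical choices and degenerate inputs

- Dunnett quadrature: 64 × 64 nodes by default (÷~1e-6 accuracy;
  cross-checked in tests against an independent QMC implementation and a
  10⁶-draw Monte-Carlo max|T| oracle at ±0.005).
- AUC: `numpy.trapezoid` on actual read times; the fine-grid Riemann
  oracle agrees to < 1e-9 relative error.
- Results CSV writes floats with `repr`, so write → read round-trips
  bit-for-bit; missing optional fields are empty strings, never sentinel
  numbers. Parsing is order-independent (canonical plate/row/col/time
  sort).
- Errors, not NaNs: duplicate wells, orphan wells, schedule violations,
  degenerate calibration designs, failed inductions, zero pooled
  variance and constant correlation inputs all raise typed exceptions.

## Problem sizes used by the test suite

Unit and property tests run on hand-sized inputs. End-to-end tests use a
56-extract campaign (two cell plates); recovery checks use the full
default 375-extract campaign; count-calibration medians use 50 truth
draws; type-I calibration uses 1000 null campaigns of 100 extracts laid
out as 4 plate families of 25 treatments, evaluated at the statistics
layer (replicate percents drawn under the null) rather than through full
plate emission. These sizes keep the whole suite around a minute while
leaving each check statistically meaningful.

## Known limitations

- Linear calibration only; no 4PL, no per-plate drift correction.
- No Welch-type heteroscedastic Dunnett; no library-wide FDR; no
  effect-size confidence intervals.
- NO is reported only relative to the LPS control (no µM nitrite).
- The viability gate is a pure threshold; no dose–response (IC50)
  modelling.
- Correlations use extract means; replicate-level uncertainty is not
  propagated into r_s.
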