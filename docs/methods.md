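# Methods

## The two indices

**WAWQI (drinking-water suitability).** Each of 13 physicochemical
parameters gets a quality rating

    Q_n = 100 · |V_n − V_i| / |S_n − V_i|

with measured value `V_n`, permissible standard `S_n` and ideal value
`V_i` (0 for all parameters except dissolved oxygen, 14.6 mg/L, and pH, 7).
The index is the weighted mean `WAWQI = Σ Q_n W_n / Σ W_n` with unit
weights `W_n = K / S_n`, `K = 1 / Σ(1/S_n)`, so Σ W_n = 1 exactly and the
weights are inversely proportional to the standards.  With the default
registry, K ≈ 0.1601 and ammonium-nitrogen (standard 0.2 mg/L) carries
≈ 0.80 of the total weight — the index is, by construction, primarily an
ammonium alarm with the remaining parameters as modifiers.  Scores bin
into Excellent (0–25], Good (25–50], Poor (50–75], Very poor (75–100] and
Unfit (> 100); the printed integer ranges are realised as half-open
intervals closing on the upper bound so continuous scores leave no gaps.

The absolute deviations in `Q_n` are a deliberate reading: a pH below 7 or
a DO above 14.6 would otherwise produce negative ratings with no defined
class.  At the ideal the rating is 0; at the standard it is exactly 100.
Two quirks of the default registry are kept as configured rather than
"fixed": water temperature enters with ideal 0 °C and standard 25 °C, so a
typical 20 °C stream already rates Q = 80 on that (low-weight) parameter,
and the nitrate standard is 13.29 mg/L.  Both are configuration, not code:
the standards file can override every value.

**CPI (ecosystem health).** Nine parameters (DO, pH, turbidity, EC,
NH₄⁺-N, NO₃⁻-N, SRP, Cl⁻, temperature) each contribute a single-factor
pollution index `PI_i = C_i / S_i`; the CPI is their arithmetic mean.  The
CPI standards equal the WAWQI ones except DO (8 mg/L), chloride (120 mg/L)
and temperature (27 °C).  Classes: No Apparent Impact (≤ 0.2), Minimal
(≤ 0.4), Slightly (≤ 1.0), Moderately (≤ 2.0), Severely Impacted (> 2.0).

*DO direction.* A literal `DO/S` falls as oxygen is depleted, rewarding
pollution.  The default therefore inverts DO (`S/DO`), so the PI rises as
oxygen falls; the literal mode remains available (`do_mode="literal"`)
and the chosen mode is stamped into every output row, because the two
conventions produce different CPI values and any comparison across runs
must hold the mode fixed.  pH enters literally as `pH/8.5` (≈ 0.82 at
neutral); a deviation-based alternative was considered and rejected as a
default for the same fidelity-to-formula reason.

**Missing data.** Both indices renormalise by default: a missing parameter
drops out of numerator and denominator (for the CPI, `n` counts the
parameters present).  This is the weighted-mean-preserving choice; a
strict mode errors instead so laboratory gaps cannot pass silently.

## The combined risk matrix

The (WAWQI, CPI) pair maps through a total 3×3 decision table to five
levels: Low Risk (WAWQI ≤ 50 and CPI ≤ 0.4), Moderate Risk (Ecosystem)
(good drinking water, impaired ecosystem), Moderate Risk (Drinking) (the
converse), High Risk (both degraded), and Severe Risk whenever either
index alone crosses its worst threshold (WAWQI > 100 or CPI > 2.0).
Thresholds close their cells from above (a station at exactly 50 / 0.4 /
100 / 2.0 stays in the milder cell), and severity is monotone: raising
either index can never improve the level.  The two Moderate variants are
deliberately unranked against each other.

Station-level classification averages the monthly index values and
classifies the pair of means (`mean-of-indices`).  The alternative —
average the raw concentrations first, then index once (`index-of-means`)
— is exposed because the two disagree in general (the index is nonlinear
through the DO inversion and the renormalisation), and reproductions of
published station classifications may need either.

## Seasonal aggregation

Dry season: January–February and June–August (5 months); wet: the rest
(7 months).  Seasonal index comparisons pool all station-months of a
season and apply the two-sided Wilcoxon rank-sum (Mann–Whitney U) test via
scipy; pooling treats station-months as exchangeable, which overstates
independence where stations differ systematically — a paired per-station
comparison is easy to run on the per-sample output table if that matters.
Station summaries are mean ± sample SD (n−1).  Risk-category percentages
are re-derived from integer counts at one decimal with round-half-even
(5/16 → 31.2%, 3/16 → 18.8%), never accumulated, and the raw fractions are
reported alongside.

## The synthetic scenario

The generator emulates one year of monthly sampling at 16 stations for 19
parameters (n = 192 station-months), for testing every pipeline stage
without downloads.  Design:

- **Cell table.** Each station×parameter cell has a target mean and SD.
  ~30 cells use published station statistics verbatim (e.g. turbidity
  82.38 ± 66.69 NTU and TSS 298.75 ± 343.81 mg/L at the dam outlet M16,
  DO 4.31 ± 1.44 mg/L below the urban discharge at M8, EC 262.25 ± 74.99
  µS/cm at M13).  Remaining cells interpolate log-linearly between the
  anchored extremes along a fixed per-station pressure score in [0, 1]
  (urban M8/M9 ≈ 0.9–0.95 and agricultural M1 = 0.85 at the top;
  north-western headwaters M3/M5/M6/M7 and M15 at 0.05–0.22).  Ammonium —
  point-source dominated and, at 80% index weight, the main WAWQI driver —
  uses explicit per-station means instead of the gradient: ~0.07–0.09 mg/L
  at the five clean stations, 0.13–0.19 mg/L in the middle band,
  0.35–0.41 mg/L at the three impacted stations.  Parameters with no
  plausible pressure ordering (temperature, chlorophyll-a, nitrate, SRP)
  take a flat default with anchors overriding.  Major ions (Na⁺, K⁺, Cl⁻,
  SO₄²⁻) and hardness have no published numbers; their ranges were chosen
  once to be consistent with the published conductivity range (74–262
  µS/cm) for a dilute tropical headwater system.
- **Seasonality** is a multiplicative factor on the cell mean only (SD
  held): wet-season turbidity ×1.4 and TSS ×1.5 (storm runoff), nutrients
  washed off fields ×1.1–1.2, while conductivity, TDS and the major ions
  dilute to ×0.85–0.9 and DO/nitrate dip slightly.  This is the simplest
  model consistent with a concentration–dilution narrative; it imposes no
  within-month correlation between parameters.
- **Noise** is lognormal with exact moment matching, μ = ln(m²/√(m²+s²)),
  σ² = ln(1 + s²/m²): several published cells have SD ≥ mean, which a
  truncated normal cannot represent without severe bias, and
  concentrations must stay positive.  pH is drawn normal on its own scale
  and clipped to [5, 9] (pH is not a concentration).  One standard-normal
  batch per cell drives all 12 months, so identical seeds give
  bit-identical datasets.

Under the default scenario the station risk pattern reproduces the
qualitative field situation: no station is ever Low Risk (the turbidity,
DO and pH terms alone keep every station's CPI above 0.4), around
two-thirds to three-quarters of stations are poor-to-unfit for drinking,
the three impacted stations classify Severe, and the remainder split
between High and Moderate (Ecosystem).  Exact per-seed counts fluctuate
by ±1–2 stations because twelve heavy-tailed monthly draws estimate each
station mean noisily — as they do in a real one-year campaign.

**What the generator does not emulate:** cross-parameter correlation
(EC–TDS near 1 in real data; independent here), serial correlation between
months, episodic pollution events beyond the lognormal tail, and any
rainfall-runoff physics.  Passing tests on synthetic data therefore
demonstrate the correctness of the index arithmetic, classification logic
and aggregation — not that the scenario is a statistically complete model
of the catchment.

## Numerical choices

- Band edges: scores within a relative 1e-12 of a class edge snap onto the
  edge, so an all-at-standard sample (exactly 100, or CPI exactly 1, in
  exact arithmetic) bands as the edge value despite float rounding.  The
  risk matrix itself uses exact comparisons; ±1e-9 perturbations around
  its thresholds classify on the correct side.
- CSVs are written with `%.17g` floats and read with round-trip parsing,
  so every numeric column survives a write/read cycle bit-identically.
  The sodium code `NA` forces `keep_default_na=False` in the reader.
- The inverted DO pollution index is undefined at DO = 0 and raises; the
  literal mode accepts 0.
- Degenerate inputs (no index parameters in a record, empty record sets,
  negative concentrations, pH outside [0, 14], months outside 1–12,
  partial season calendars) raise `ValueError` with the offending station
  /parameter named; the lenient reader skips and logs instead.

## Interfaces

The scoring core follows the sklearn estimator contract (`WawqiScorer`,
`CpiScorer` as transformers over parameter-column DataFrames,
`RiskClassifier.predict` over (wawqi, cpi) pairs), so the components
compose with sklearn pipelines; `compute_wawqi` / `compute_cpi` /
`classify_risk` are thin single-sample wrappers.  The `aquarisk` CLI
(`simulate`, `wawqi`, `cpi`, `risk`, `report`) covers the shell workflow;
every run log records the config and a SHA-256 of the standards table,
because index values are meaningless without the standards that produced
them.

Externally published monitoring tables load through a `ColumnMapping`
adapter (long or wide layout, arbitrary column aliases).  The packaged
template for the public Maziba deposit is best-effort: its column aliases
must be checked against the downloaded files before use.

## Known limitations

- The WAWQI's extreme ammonium weighting means the other twelve
  parameters can barely move a classification; this is a property of the
  published weighting scheme, faithfully implemented, not of this package.
- The seasonal test's pooling assumption (above).
- The acceptance checks that recompute published station statistics
  require the deposited dataset to be downloaded into `data/zenodo/`;
  they fail with instructions when it is absent.
- Problem sizes in the test-suite simulations (5,000 draws per cell for
  moment recovery, 200 replicates of the 16×12 campaign for seasonal
  power) were chosen as the smallest sizes at which the binomial/Monte
  Carlo error is comfortably below the asserted margins.
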