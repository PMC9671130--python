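# Methods

## Model

`nload` simulates annual nitrogen delivery from parcel-level sources to
estuaries as a discrete-delay mass balance. Each parcel is characterized by
the year it began loading (year built), a raw load (kg N/yr entering
groundwater), a single combined attenuation fraction (removal by soils,
ponds, and wetlands en route), a groundwater travel time, sewer status, and
a potential buildout increment. The attenuated rate
`r = raw × (1 − attenuation)` enters the aquifer over the parcel's *input
window*; mass input in year `y` arrives at the bay in year `y + τ` with
`τ = floor(travel_time)` (the annual step makes sub-year resolution
meaningless). The delivered series for a watershed is the sum of its
parcels' shifted window indicators times their rates.

Assumptions worth keeping in mind:

* **Plug flow, no dispersion.** A parcel's mass arrives after exactly its
  travel time; there is no smearing of arrival times. Real plumes disperse,
  so observed transitions are smoother than the simulated steps.
* **Constant per-parcel rates.** Loads do not vary with occupancy,
  season, or water use; a parcel loads at its full rate from its start
  year on.
* **Attenuation is one multiplicative fraction per parcel**, not a chain of
  modelled features; the concentration helper
  `attenuate_concentration(initial, factors)` exposes the chain form for
  back-of-envelope work.
* **No in-bay processes.** Residence time, sediment flux, and atmospheric
  deposition are outside scope; the output is watershed (controllable)
  load at the bay, not in-water concentration.

### Simulation window and arrival rule

The grid runs 1880–2150 with the "current" year at 2020. Construction
years before 1880 are clamped to 1880 rather than rejected — old town
centers predate the window, and for delivery purposes an 1850 start is
indistinguishable from 1880 after 140+ years.

`arrival_rule` pins a one-year ambiguity: under the default `inclusive`
rule, input in year `y` first arrives in `y + τ`; under `strict`, in
`y + τ + 1`. The strict reading matches a strict inequality sometimes used
for buildout contributions; the inclusive default applies one symmetric
convention to all contributions. The choice shifts every series by at most
one year and never changes a qualitative conclusion, but it must be fixed
for reproducibility, so it is a config flag with the engine applying one
rule uniformly.

### Scenarios

* **Status quo**: no events; series are non-decreasing.
* **Buildout** (upper bound): each parcel with a positive buildout
  increment receives it at one year drawn uniformly from 2020–2039 (20
  event years; the window's phrasing as "2020 to 2040" is implemented as
  20 years starting 2020). Base loads continue; no source control.
* **Source control** (lower bound): all unsewered parcels with positive
  load are shut off; a uniform random permutation fixes the order and
  parcels are spread evenly over the 20 window years
  (quota `ceil(n/20)`, remainder in the earliest years). Shutoff removes
  future input only — mass already in the aquifer still arrives.
  Shutoff is modelled as full elimination of the parcel's delivered
  contribution, not reduction to an advanced-septic residual.
* **Legacy**: every input window is truncated at 2019 and arrivals are
  tallied over 2025–2150. The 2025 tally start excludes mass with less
  than five years left in transit; because that convention is not
  self-evident, a companion total over 2020–2150 is always reported
  (`mass_from_shutoff_kg` / `legacy_mass_from_shutoff_tons`).

Monte Carlo ensembles default to 1000 iterations. Sub-seeds are derived as
`SeedSequence([master_seed, iteration_index])`, so iteration *k* can be
replayed alone and results are bit-identical for a given master seed.
Envelopes store per-year min/mean/max per watershed.

### Equilibrium diagnostics

For a status-quo series, `ratio = max_{t>2020} L(t) / L(2020)`. A
watershed is in equilibrium when `ratio ≤ 1 + ε` with ε defaulting to 0.01
("at or near 1"); `StatusQuoResults.equilibrium(epsilon=...)` makes the
sensitivity sweep (e.g. ε ∈ {0.001, 0.01, 0.05}) one-line. Years to
equilibrium is the first year the series reaches `(1 − ε)` of its future
maximum, minus 2020, clamped at 0; using the near-maximum crossing rather
than the exact maximum avoids declaring a century-long wait for a final
fraction of a kilogram at the horizon edge. A zero current load with
nonzero future load reports an infinite ratio and `in_equilibrium=False`.

Per-watershed summaries (property count, mean/sd year built, mean/sd
travel time, maximal annual load) use the sample (n − 1) standard
deviation, reported missing when a column has fewer than two distinct
values — the natural reading of a blank spread for a watershed whose
parcels all fall in a single travel-time zone. The "annual maximal load"
is the maximum of the status-quo series over the whole horizon, i.e. the
load at equilibrium.

### Worked-example arithmetic

`cagr(g, n) = (1+g)^{1/n} − 1` converts total growth to a compound annual
rate (2.5% over 8 years → 0.31%/yr). Note that a 12.1% buildout over 20
years corresponds to `cagr(0.121, 20) ≈ 0.57 %`/yr by this formula; a
figure of 0.53%/yr sometimes quoted for that assumption does not follow
from the compound-growth identity and is not reproduced here.
`net_concentration_reduction(delivered, treated)` floors at zero: in this
accounting, treatment cannot add net load.

## Synthetic-region generator

The generator produces attribute-only parcel tables shaped like a
septic-dominated coastal region. Defaults (one choice, used everywhere):

| parameter | default | rationale |
|---|---|---|
| watersheds | 54 | study-region count |
| parcels per watershed | log-uniform 6–9500 | observed counts span 3 orders of magnitude |
| year built | N(1965, 35²), truncated 1880–2020, rounded | mid-century building boom with long tails |
| watershed mean travel time | U(5, 47) yr | observed watershed means |
| parcel travel time | lognormal, cv = 1, capped 150 yr | within-watershed sd ≈ mean (heavy right tail) |
| raw load | lognormal(meanlog 1.87, sdlog 1.2) kg/yr | median ≈ 6.5 kg/yr; per-parcel delivered loads of a few to tens of kg |
| attenuation mixture | none 0.60 / pond 0.25 @ 0.40 / pond+wetland 0.15 @ 0.64 | 0.64 = 1 − 0.6², two features each removing 40% |
| sewered fraction | 0.15 | mostly unsewered region |
| buildable fraction | 0.121 | documented 20-year buildout share |
| buildout increment | 1.0 × raw load | a developed parcel roughly doubles its load |
| TMDL fraction | 0.57 | just over half of bays regulated |

Travel time, year built, and load are drawn independently within a
watershed; any real correlation (e.g. newer homes farther from shore,
hence longer travel times) is not represented. Parcels built before 1880
are not generated — the clamping path is covered by a dedicated fixture in
the tests. Because the generator is calibrated to marginal ranges only,
passing tests demonstrate the *mechanics* (mass conservation, ordering,
determinism, moment recovery), not that any particular real watershed's
trajectory is reproduced.

## Numerical choices

* The production series builder uses interval (slice) addition; an
  exhaustive packet enumeration (`packet_oracle`) is kept in the package
  and the two are asserted equal — exactly, no tolerance, since both sum
  identical addends — on randomized instances in the tests.
* Legacy masses are cross-checked against an independent per-parcel
  closed-form overlap count.
* Open input windows are capped at 2150 internally; series never extend
  past the horizon.
* CSV round-tripping writes floats with `%.17g` and reads with
  pandas' `round_trip` parser, so read(write(table)) is field-for-field
  identical.
* Degenerate cases: empty parcel tables yield empty outputs (never
  errors); a window whose shutoff precedes its start contributes nothing;
  zero current load marks "multiples of current" missing rather than
  dividing by zero.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full pipeline on
regions of 54 watersheds at roughly 150–260 parcels each (~11,000 parcels)
with 25–50 Monte Carlo iterations, and the engine-vs-oracle and legacy
closed-form checks on hundreds of randomized instances of up to 100
parcels over the full 271-year horizon. These sizes exercise every code
path at full structural fidelity; scaling to the full region (~90,000
parcels, 1000 iterations) is a linear cost increase in both parcels and
iterations.

## Known limitations

* One travel time per parcel; no within-parcel travel-time distribution.
* Scheduling in the source-control scenario is a uniform random order;
  real sewer programs proceed in spatially contiguous neighborhoods, which
  would narrow the envelope.
* No geometry, so no mapping outputs.
* The buildout scenario adds increments only to parcels flagged buildable
  at generation/input time; it does not create new parcels.
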