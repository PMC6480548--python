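# Methods

This note documents the model implemented by `rems`, the choices made where
the design was genuinely open, the synthetic-data generator's construction,
and the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The system estimates quarterly **unit expenditure per service** at health
facilities by linking two routine data streams:

* an expenditure ledger keyed by hierarchical account codes
  (`head/department/unit/programme[/activity]`), with each record controlled
  by one unit of a strict four-level administrative tree
  (national → provincial → district → facility);
* facility-level service output counts per calendar quarter.

Three elicited/assessed inputs drive the allocation:

1. **HIV-share weights** (account prefix → fraction in [0, 1]): the portion
   of an account's spending that supports HIV services. Matching is by the
   most specific prefix; an account matching nothing defaults to share 0
   (non-HIV). Two equally specific matching patterns are a configuration
   error, not a tie-break.
2. **Flow-down rules** (account prefix × controlling unit): a retained
   share (kept at that level as an *above-facility* expense) plus explicit
   child shares summing, with the retained share, to 1. A rule with no
   explicit children and retained < 1 splits the remainder across children
   in proportion to the number of facilities beneath each — the documented
   fallback when an informant says "flows down" without an apportionment
   basis. Rules are time-invariant within a run (one elicitation applied to
   all quarters).
3. **Facility assessments** (ingredients approach): line items with annual
   quantity × standard unit cost. Capital categories are annualized
   straight-line over a configurable useful life (defaults: equipment
   5 years, vehicles 8 years; an item-level life overrides the default).
   Dedicated items map wholly to their service; shared items are
   apportioned proportionally to `sessions_per_week × relative_annual_volume`
   over the facility's scheduled services. This multiplicative form honours
   both availability and volume and reduces to pure volume-proportionality
   when session counts are equal. The resulting annual operational budget
   yields the **Resource Allocation Matrix**: per-facility weights
   `w(service, category) = cell cost / budget total`, nonnegative and
   summing to 1. RAMs are annual and time-invariant within a run.

The cascade is linear and conservative: facility-controlled records pass
through whole; higher-level records are split recursively. For every
quarter and funding source the engine asserts
`|Σ inflows + Σ above-facility − Σ HIV-share ledger| ≤ 1e-6` currency units
and the test suite cross-checks the engine against an independent
path-enumeration oracle.

Unit expenditure divides each facility's allocated service amount by the
same-quarter output volume. Zero volume, missing volume, and zero
expenditure are distinct record statuses; division never occurs for them.
Missing is deliberately not zero: an omission in the output system must
remain visible. Group-level (district/province) unit expenditure is the
volume-weighted ratio of sums `Σ amount ÷ Σ volume`, which preserves
conservation under aggregation; the mean of facility unit costs is exported
only as a diagnostic column.

Outlier flags use a robust z-score, `(x − median) / (1.4826 · MAD)`, within
comparison groups of same geographic scope × service × quarter (default
scope: district). A record is flagged when |z| > 3 and the group has ≥ 5
members; MAD = 0 groups and too-small groups produce notes, never flags.
The threshold, minimum group size and scope are configuration. The robust
rule is this package's stated choice of "standard"; the source system's
standard is a managerial judgement, not a published formula.

## Key parameters

| Parameter | Default | Unit | Rationale |
|---|---|---|---|
| `negative_amount_policy` | `net` | — | journal corrections net within their key; a key netting negative is an error (preserves quarter totals) |
| `default_hiv_share` | 0 | fraction | unmatched accounts are non-HIV |
| `useful_life_years` | equipment 5, vehicles 8 | years | standard straight-line horizons for clinical equipment and vehicles |
| `outlier_threshold` | 3 | robust z | conventional 3-sigma-equivalent cutoff |
| `outlier_min_group` | 5 | facilities | below this, a median/MAD comparison is not meaningful |
| `conservation_tol` | 1e-6 | currency | float-summation slack on exact money identities |

## Synthetic-data generator

Generation is **truth-first**: the recovery targets are fixed before any
input table exists, making the pipeline falsifiable end-to-end.

1. A balanced hierarchy is built (defaults: 2 provinces × 2 districts ×
   3 facilities, facility types cycling hospital / urban health centre /
   rural health centre) over 4 quarters starting 2016Q1.
2. Per (facility, service), a quarterly volume is drawn once from a
   negative-binomial (means by facility type and service, on the order of
   25–1,500 visits/quarter; dispersion 8) and held constant across quarters.
   True unit costs are fixed per (facility type, service) in the range
   60–900 Kwacha per visit, consistent with the order of magnitude of
   published EMTCT visit costs (~125–1,337 Kwacha).
3. True service expenditure is `true_unit_cost × volume × (1 + ε)`, with one
   multiplicative noise draw ε ~ N(0, sd) per facility-quarter (default
   sd = 0.1, clipped far in the left tail to keep ledger amounts positive).
4. The ledger is synthesized backwards: a fraction (default 0.5) of each
   facility's baseline requirement is routed through a national chain
   account whose flow-down rules split proportionally to baseline
   requirements and retain the configured above-facility fractions
   (defaults: 10% national, 6% provincial, 4% district); the remainder plus
   the noise term arrives on a facility-controlled account. HIV-share
   weights (facility accounts 0.6, chain 0.8) gross the HIV amounts up into
   larger ledger totals, and a decoy non-HIV account exercises the default
   share. Assessments contain one dedicated line per service × category
   whose costs reproduce the per-service category mix exactly.

Two constructions make **exact noiseless recovery** possible under an
annual, time-invariant RAM: constant within-facility service mix across
quarters (volumes drawn once), and facility-level (not service-level)
multiplicative noise. Real data respect neither — caseload mix drifts
seasonally, and ledger errors are not proportional across an entire
facility — so passing recovery tests demonstrates the correctness of the
allocation arithmetic, not robustness to structural mis-specification of
the RAM. The generator also idealizes assessments as fully dedicated line
items; shared-resource apportionment is exercised by its own unit tests
rather than by the generator, because a shared split keyed to
session-weighted service volumes cannot in general reproduce an arbitrary
target category mix. Synthetic ledger amounts are written at full float
precision (a real ledger is cent-grained; the exactness of recovery, not
realism of the last digit, is what the harness needs).

The single RNG stream per bundle draws in a fixed documented order
(volumes, then noise factors, then decoy amounts), so adding downstream
fault types never perturbs earlier draws; fault injection (`corrupt`)
operates on the finished tables and records a manifest.

## Numerical conventions

* Ledger ingest sums duplicate keys in decimal arithmetic; allocation runs
  in floating point with the 1e-6 conservation tolerance above.
* Written tables are deterministic (fixed column order, all key columns
  sorted ascending, UTF-8, quoted text, LF). Currency serializes at 2
  decimals, round-half-even, with a largest-remainder adjustment within
  each (facility, quarter, funding source) group so written rows sum to
  the written totals.
* Because intermediate tables are cent-rounded, running the stage commands
  file-by-file matches the end-to-end driver only to cent-level differences
  in unit values; the driver itself carries full precision between stages.
* RAM weights are renormalized after construction so the sum-to-1 invariant
  holds exactly; weight serialization uses 12 significant digits and
  re-normalizes on load.
* Ties in medians use the standard midpoint; a facility exactly at its
  group median always has robust z = 0 and is never flagged.

## Problem sizes

The test suite and acceptance checks run on deliberately small instances —
conservation across 100 random scenarios of 1–2 provinces and 1–3
facilities per district, oracle equivalence at 50 accounts × 20 facilities
× 5 services, unbiasedness at 200 facility-quarters, and 1,000 random
budgets for RAM invariants — sizes at which the brute-force oracles remain
exact and fast while exercising every code path. The engine itself is
linear in (records × path length) and handles the full production scale
(hundreds of facilities) without modification.

## Known limitations

* Calendar quarters only; fiscal-year ledgers must be pre-normalized.
* Community-level delivery is an attribute of facility services, not a
  fifth hierarchy level.
* One RAM covers HIV services only; non-HIV activity must be excluded
  upstream by the HIV-share weights.
* No currency conversion or inflation adjustment across quarters.
* Flow-down weights are taken as given; the package does not estimate them
  from data, and centrally procured commodities are treated as ordinary
  accounts rather than cascaded by consumption.
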