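# Methods

## The data model

A `QcRecord` is one sample's quality dossier: a record identifier, an
optional patient reference, and four workflow-stage blocks covering the
clinical NGS pipeline — sample preparation (assay type, panel genes,
specimen type, sampling date), library preparation split into DNA
extraction (kit, OD 260/280 and OD 260/230 purity ratios, median fragment
size in bp) and library construction (input amount in ng, input size in
bp, kit), sequencing (instrument, read length, direction, running mode,
error rate, percent ≥ Q30), and data processing (total reads, mean
coverage, uniformity, on-target rate, Q30, pass-rate score, plus the
software/criteria provenance strings). Every element is declared once in
`ngsqr.elements` with its dotted path, its position in the extension
tree, its semantic type, its unit and its admissible range; all other
modules are generated from that registry, so the flat view and the FHIR
view cannot drift apart. There are 30 such elements plus the two
identifiers.

Two deliberate modelling choices: percent-of-bases-≥-Q30 appears twice
(`sequencing.pct_q30` as run quality, `processing.q30` as pipeline
quality) because the workflow reports it at both stages, and the two are
not reconciled; and the pass-rate (PR) score is carried as an opaque
percentage — it is a laboratory-reported aggregate with no public
formula, so the package transports it but never derives it.

Construction (`make_record`) coerces types only — strings to numbers,
ISO-8601 strings to dates, code strings to enums; `"85.0"` becomes the
decimal 85.0. Range checking is separate (`validate_record`) and
report-based: out-of-range values are *errors*, absent elements are
*warnings*. Nothing beyond the record id and the stage blocks is
structurally mandatory, because no published cardinality exists for
these elements; receivers can promote warnings to errors via their own
policy. All percentages are on the 0–100 scale, never 0–1.

## The FHIR layer

A record is exchanged as a FHIR R4 `MolecularSequence` resource whose
QC payload lives in one extension tree under the canonical url
`http://example.org/fhir/StructureDefinition/QcMetrics` (configurable).
Nesting is stage → optional group → field, maximum depth four
(e.g. `dnaExtraction → dnaPurity → od260280`).

Legacy emitters put a `"units"` key *next to* `valueDecimal` inside an
extension (`{"url": "dnaIntegrity", "units": "bp", "valueDecimal":
60000}`). That is not legal R4 extension syntax — extensions carry only
`url` + one `value[x]` — but archived resources exist in that shape, so
the codec supports it as the `paper` dialect and reproduces it exactly,
down to serializing integral decimals without a trailing `.0` so output
is byte-comparable. The `strict_fhir` dialect (default for writing)
encodes unit-bearing leaves as `valueQuantity {value, unit}` with the
unit strings `bp`, `ng`, `%`, `x`. Reading auto-detects: any `units`
sibling, or a bare numeric value under a unit-bearing element, implies
the legacy dialect; otherwise strict. Enumerated codes travel as
`valueString` in both dialects for fidelity with the legacy layout.

Parsing is tolerant: unknown sub-extensions are collected in an
ignored-elements list (FHIR extensions are open by design) and numeric
values arriving as strings are coerced. Two things are fatal: a wrong
`resourceType`, and a leaf carrying both `units` and `valueQuantity`
(genuinely ambiguous). `validate_resource` is stricter than `from_fhir`
on purpose: it checks the exact `value[x]` key per element and dialect,
warns on unknown urls, and then delegates value ranges to the domain
validator.

`emit_profile` derives a `StructureDefinition` (derivation
`constraint` on `MolecularSequence`) from the same registry: one leaf
element definition per data element (30 leaves), cardinality 0..1
except the repeated gene-symbol element (0..*), unit-bearing leaves
typed `Quantity`. Because profile and codec share one source of truth,
every leaf the codec can emit is in the profile by construction — the
test suite still asserts it.

## The store

One canonical-JSON file per resource under a root directory, with an
id index rebuilt from the directory on open — the simplest crash-safe
layout; re-opening a store reproduces documents bit-exactly. `create`
follows POST semantics (server-assigned numeric ids; idempotent per
client id, conflict on content mismatch), and validates before
persisting. Search parses stored resources on the fly (O(n), adequate
at desk scale ~10⁴; unparseable resources are skipped, logged and
tallied) and applies conjunctive facet filters: specimen type,
sequencing type, sampling year, and one numeric metric range. Records
without a sampling date never match a year filter. `push_remote`
implements the FHIR client contract — POST to
`{endpoint}/MolecularSequence` with a caller-supplied bearer token —
and is tested against a local stub server; token acquisition (OAuth
flows) is explicitly out of scope.

## Statistics conventions

* **Quantiles**: linear interpolation between order statistics (numpy's
  default; identical to `statistics.quantiles(..., method="inclusive")`).
* **Spread**: sample sd, n−1 denominator; absent for n < 2.
* **Percentile of a sample in a group**: mid-rank,
  `100·(#{x < v} + ½·#{x = v})/n` — deterministic under ties, bounded
  [0, 100], monotone in v.
* **z-score**: `(v − mean)/sd`; absent when sd is absent or zero.
* **Missing values**: excluded per metric, never imputed; every summary
  reports `n` and `n_missing` so the denominator is visible.
* **Rank-sum test** (`compare_groups(..., rank_sum=True)`): two-sided
  normal approximation to the Wilcoxon rank-sum statistic with the
  standard tie correction and *no* continuity correction; reported only
  when both groups have ≥ 8 non-missing values, and off by default —
  the comparison's primary output is the pair of distribution summaries
  and the median difference, not a p-value.
* Group values are sorted before aggregation so all statistics are
  exactly permutation-invariant (fixed summation order).
* No default thresholds are active; they come from user config only
  (see `docs/thresholds.example.yaml`).

## The synthetic generator

The generator emulates the accumulated QC table of a targeted cancer
panel operating for several years: default n = 1000 records, specimen
mix 60% FFPE / 30% fresh cell / 10% cell line, sampling dates uniform
over 2014–2020, all targeted-panel assays with 3–8 genes drawn from a
12-gene pool, and categorical fields (kits, instruments, software)
drawn from weighted pools.

Numeric metrics are drawn per specimen-type profile from one of three
families — truncated normal, lognormal (`loc` is the median), or scaled
Beta on a fixed interval — with truncation bounds respecting each
metric's domain (percentages to [0, 100], sizes and amounts positive),
so **every generated record validates clean by construction**. The
three shipped profiles order location parameters so that fresh-cell ≥
cell-line > FFPE for the quality-increasing metrics (DNA median size,
percent ≥ Q30, mean coverage, uniformity, on-target rate, PR score) and
the reverse for error rate — the qualitative signature of formalin
fixation, which fragments and damages DNA. **All profile constants are
invented, illustrative values** chosen to be plausible for deep
targeted panel sequencing (e.g. FFPE median fragment size ~3 kb vs
~50 kb fresh; mean coverage ~620× vs ~900×); they are not fitted to any
real laboratory's data, and the cell-line profile's placement between
the other two is an assumption, not an observation. Everything is
overridable through `GeneratorConfig`.

Determinism: each record is drawn from its own PCG64 stream seeded by
`SeedSequence((master_seed, record_index))`, so generation is
order-independent and identical (config, seed) pairs reproduce datasets
byte-for-byte across platforms. Specimen counts use largest-remainder
apportionment of the mix proportions (ties broken by mix order), which
makes the per-facet tallies exact constants rather than random draws —
the tallies double as ground truth for the count-conservation tests.
Small missingness rates (2–5%) apply to the optional wet-lab
measurements; identifiers, specimen type and sampling date are always
present.

What passing tests on synthetic data do and do not show: they verify
the plumbing (lossless round trips, exact counting, correct statistics,
violation detection) and the *direction* of specimen-type effects under
the shipped profiles; they say nothing about real effect sizes,
real missingness structure, batch effects, or instrument drift, none of
which the generator models.

`corrupt` injects documented violation classes for negative-path
testing — out-of-range percentage and negative size at the record
level; wrong `value[x]` key and unknown sub-extension at the encoded-
resource level (those two only exist after encoding) — on a seeded
random subset, returning the injected (id, path, class) triples so
tests can assert detection is exact, with no misses and no spurious
flags.

## Problem sizes used by the verification scripts

The test suite and `scripts/acceptance.py` use cohorts of 60–1000
records, 100 random small groups for the statistics oracle, a
500-resource store for count conservation, and 50 seeded cohorts of
200 per group for the specimen-ordering property — sizes at which every
checked property is already stable while the whole verification run
stays fast on a laptop.

## Known limitations

* No terminology bindings (LOINC/SNOMED) — the element set predates any
  public binding, and none are invented here.
* The `MolecularSequence` sequence/variant elements themselves are
  referenced, not populated; this package carries QC metadata only.
* The legacy dialect reproduces the one archived layout we have; if
  real emitters placed `units` elsewhere, those variants are unknown
  and unhandled.
* Search is a linear scan; beyond ~10⁴ resources a real FHIR server is
  the right tool.
* XML serialization, FHIR versions other than R4, transaction bundles,
  and web UIs are out of scope.
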