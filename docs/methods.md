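# Methods

## The cytological coordinate system

Each chromosome is modeled as its SC axis: a 1-D micrometer coordinate
from the short-arm telomere (0) through the kinetochore center
(`arm_short_um`) to the long-arm telomere. The axis is tiled by half-open
chromatin segments `[start, end)` of classes euchromatin, heterochromatin,
kinetochore, NOR, chromomere and border; a position on a boundary belongs
to the segment starting there, and the long-arm telomere to the last
segment, so classification is total and unambiguous. Arm-relative
measurements (distance from the kinetochore center along one arm) convert
to axis positions by `short: L_s − d`, `long: L_s + d`, an exact bijection.

The kinetochore is a ~1 µm segment (configurable) centered on the arm
junction, matching its appearance as a ~1 µm disk on spreads. Chromosome
identity and the euchromatin/heterochromatin border positions are inputs
to the model, not inferred: spreads do not carry that information in this
pipeline's scope.

## Measurement model and averaging order

A focus observation is `(spread, probe, arm, distance, arm_length)`.
Because spreads differ in absolute SC length, fractions `d/L` are averaged
across spreads *first* and only then rescaled by the model's mean arm
length. With variable arm lengths this differs from averaging micrometer
positions; the fraction-first order is the field convention and is what
the package implements (an algebraic-identity test covers the
constant-arm-length case where they coincide). Per-probe SDs are computed
in µm space (per-spread fraction × mean arm length), the scale on which
the canonical "≈0.1 µm per BAC" precision statement is made; whether
fraction- or µm-space SDs were historically used is not standardized, and
µm space was chosen for that comparability.

No outlier rejection is applied by default; a median-absolute-deviation
filter is available (`mad_filter`) but off, since routine practice
averages all spreads. Probes observed on two arms or chromosomes are
excluded from inference and reported separately (real studies see a
handful of such two-site BACs).

## Linear DNA density

A FISH signal marks the *center* of its BAC, so the DNA between two
signals on one scaffold is the distance between anchor centers
(`(c_right − c_left)/10⁶` Mb). This single rule reproduces both standard
corrections: for true border BACs it equals the scaffold size minus half
of each border BAC; for a more internal anchor it subtracts all DNA distal
to the signal. Scaffolds whose focus interval crosses a chromatin-class
boundary are excluded from density estimation (and logged); kinetochore
observations additionally require the two anchors to flank the kinetochore
with no other class between.

Per class, observations pool as **total Mb / total µm** rather than a mean
of per-scaffold ratios: longer intervals carry proportionally more
information and the pooled form is scale-consistent (the historical
pooling rule for these estimates is not published; this is the package's
choice, recorded here). Classes with no observation keep their configured
defaults — 1.5 (euchromatin), 8.8 (heterochromatin), 3.3 (kinetochore)
Mb/µm — and are flagged. NOR, chromomere and border segments default to
the heterochromatin value (they are heterochromatin-like in compaction)
unless configured otherwise.

## Arrangement inference

Scaffolds are ordered per chromosome by the midpoint of their known border
foci — robust to a missing focus and insensitive to scaffold length —
with ties broken by scaffold id and flagged. Orientation is `forward` when
the head focus precedes the tail focus on the axis, `reverse` when it
follows, and `unknown` when only one focus exists or the two foci are
closer than the orientation margin. The margin defaults to twice the
larger of the two focus SDs: foci that cannot be resolved against their
own measurement noise should not yield an orientation call. There is no
published numeric criterion for this; the margin rule is this package's
definition and is configurable.

Kinetochore location compares the kinetochore center with each scaffold's
focus interval extended by its *overhang* DNA — from each border-anchor
center to the scaffold end it marks, converted to µm at the density of the
class at that focus — and reports `in_scaffold` or `in_gap(left, right)`.
For single-anchor (orientation-unknown) scaffolds, half the scaffold is
assumed on each side of the focus; with a centrally chosen single BAC this
is exact.

## Gap estimation

For the junction between consecutive scaffolds, the flanking foci are the
left scaffold's higher-axis focus and the right scaffold's lower-axis
focus. If the measured distance `d` is below `resolution_threshold_um`
(default 0.2 µm — a conservative bound for light microscopy; the canonical
"just below resolution" default of 0.1 µm is then *assigned* as `d` and
flagged). Gap DNA is

```
G = max(Mb(d) − overhang_left − overhang_right, 0)
```

with clamping to 0 kb recorded. Overhangs are orientation-aware: a
reversed scaffold presents its physical head to the gap. `Mb(d)` defaults
to a piecewise sum over the chromatin segments the inter-focus interval
crosses; a strict single-class mode using the class at the gap midpoint is
available (`class_mode="midpoint"`) because genome-wide gap tables have
historically been computed with a single "chromatin type involved" per
gap and the two conventions differ only for boundary-spanning gaps.
Default-distance gaps always use the midpoint class (a piecewise integral
over an assigned, not measured, interval would be spurious precision).

Totals are grouped by chromatin class, and the genome fraction is reported
as a whole-number percent of a configured genome size.

## Concordance

Order discordance between two arrangements uses positional-index mismatch:
a scaffold is order-discordant iff its rank differs, so both members of an
adjacent swap count — this matches how per-chromosome discordance lists
are tallied in practice. An LCS-based rule (scaffolds off a longest common
subsequence) is available for sensitivity analysis. Orientation
discordance requires known orientations on both sides; unknown-orientation
scaffolds can be `same` or `order_only` only. The classification is
symmetric in its two arguments. Mb aggregates use assembled scaffold
lengths.

A superscaffold is compatible with an arrangement iff its members occupy
consecutive ranks in order with matching orientations, or its full
reversal (order reversed, orientations flipped) does; arrangement-side
unknown orientations match anything.

The bundled tomato dataset encodes the SL2.40 linkage-based arrangement
(identity order, nominal forward orientations) against the FISH-determined
one for all 12 chromosomes / 91 scaffolds. Rank assignments follow the
published per-chromosome change lists (each scaffold reported at a changed
position receives a changed rank; kinetochore-adjacent run orders follow
the described gap namings where given); orientation flips are applied as
listed, and the three identifiable single-BAC scaffolds (chr1 s7, chr8 s7,
chr9 s2) are orientation-unknown. Under the positional rule the comparison
yields 45 discordant scaffolds, 28 order-only (and 2 orientation-only /
15 both — per-chromosome text tallies; the summary triple printed
alongside the 45/28 in the original report does not reconcile with its own
per-chromosome lists, so only 45 and 28 are treated as reproducible).

## Synthetic data: what it emulates and what it does not

`simulate_genome` builds chromosomes with the canonical
eu|het|kinetochore|het|eu layout, default arms 8/12 µm (±15% across
chromosomes) and 36% of each arm's axis pericentric heterochromatin —
with the default densities this puts roughly three-quarters of the DNA in
heterochromatin, as in tomato. Scaffold counts default to 8 per chromosome
(~90 genome-wide), gaps draw uniformly from 0–3.2 Mb, BAC inserts from
N(100 kb, 10 kb) clipped to 30–250 kb; scaffolds under 400 kb (planted at
rate `small_scaffold_rate`) carry one centrally placed BAC, all others a
head and a tail BAC at their ends. Unassigned probes (default one per
chromosome) are dropped into gaps. DNA is conserved exactly: scaffolds
plus gaps tile each chromosome's DNA content to the base pair.

`simulate_spreads` draws a per-spread, per-arm length factor
(multiplicative, CV 0.1 — the inter-spread arm-length CV is not published;
0.1 is a realistic order and configurable) and adds Normal focus noise of
SD 0.1 µm *in µm space* (matching how measurement precision is quoted),
truncating to the arm. Ten spreads per probe by default.
`scramble_arrangement` corrupts the truth with adjacent transpositions and
orientation flips at higher rates for heterochromatin-resident scaffolds
(defaults 0.5/0.3 vs 0.05/0.03), emulating linkage-map failure where
crossing over is suppressed. `simulate_superscaffolds` emits maximal runs
of truly adjacent scaffolds at a configurable coverage with noisy junction
gaps — evidence-level simulation only; no restriction-site or molecule
imaging model.

Not emulated: micrograph images and focus detection, probe
cross-hybridization and repeat blocking failures, chromosome
misidentification, spread-to-spread correlation of measurement errors, and
scaffold-internal assembly errors. Passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to those real-data failure modes.

All randomness derives from one master seed with per-operation substreams
(`default_rng([seed, op])`), so stages re-run independently and
deterministically.

## Numerical conventions and degenerate inputs

- Coordinates: 0-based half-open internally and in BED; AGP is 1-based
  inclusive; conversions are round-trip tested.
- Gap bp in AGP: rounded half-up from Mb; clamped/zero gaps serialize at a
  100-bp minimum so builds stay valid, with the true 0-kb calls kept in
  the gap table; unmeasurable junctions become U (unknown-size) lines.
  FISH-derived joins use the AGP evidence term `map` (noted as FISH in the
  header comment).
- Segment-boundary positions classify to the right (half-open tiling);
  ordering ties break by scaffold id with a warning.
- Anchoring is exact-match only (tags are exact-copy probes; no sequencing
  error model) and demands uniqueness; any multiplicity or inconsistent
  pairing is `ambiguous`, never guessed. A precomputed anchor table can
  bypass sequence search.
- Scaffolds with no reliable anchor are excluded downstream and reported;
  a long scaffold with one anchor keeps position but not orientation.

## Test and simulation scale

Routine tests run 1–3 chromosomes with 3–10 scaffolds each; Monte-Carlo
checks use 20 seeds (density recovery, gap-bias) or 50 replicates (order
recovery), sizes at which the suite completes in well under a minute while
the estimators' sampling error is already far inside the asserted
tolerances. Sequence-level anchoring tests use the `SimConfig.nano` preset
(~400-kb chromosomes, 20-kb inserts, 100-bp end reads) so real nucleotide
round trips stay cheap; all bp-scale parameters shrink together and the
density/noise structure is unchanged.

## Known limitations

- Density estimation uses only scaffolds wholly inside one chromatin
  class; in genomes with very fragmented class structure few observations
  may qualify and defaults then apply (flagged).
- Orientation calls near the resolution margin depend on the configured
  margin rule; there is no field-standard numeric criterion.
- The overhang-to-µm conversion uses the chromatin class at the focus
  position; an overhang spanning a class boundary is converted at a single
  density.
- Gap estimates for unresolvable foci are assigned, not measured (0.1 µm),
  and inherit that convention's bias; clamped 0-kb gaps are lower bounds.
- The scrambler applies single adjacent transpositions per marked
  scaffold; it does not simulate long-range translocations between
  chromosomes (none are expected from linkage maps, which assign
  chromosomes correctly).
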