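# Methods

This note documents the models and procedures implemented in
`lipidtraffic`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Input model

The unit of analysis is the *lipid variable*: a distinct lipid identity
after canonicalisation.  Names are parsed from shorthand
(`CLASS(c:d)` sum composition or `CLASS(c1:d1/.../cn:dn)` molecular
resolution).  Canonicalisation treats chain order as meaningless
(sn-position is not encoded), strips adduct annotations (`+NH4`, ...) and
sums adduct rows of one identity within a replicate, maps the sphingolipid
subclasses SM/Cer/HexCer/DhSph to the umbrella reporting class **SLs**,
and merges DG fragments into **TG** by default (DGs in these data arise
from in-source fragmentation of TGs; `merge_dg=False` keeps them
separate).  Ether/plasmalogen species (`O-`/`P-`) are accepted and
flagged; they are excluded from odd-chain logic by default because the
ether linkage changes the parity bookkeeping of the glycerol-bound chains.
Unparseable names are never dropped silently: they are rejected with the
offending token, or collected row-by-row into an issues table by the run
drivers.

## Compartment network

The system is an undirected graph of named compartments.  The method is
network-generic; the shipped default mouse network is plasma↔{each of 9
tissues} plus small intestine↔liver.  Because reasonable readers may also
treat adipose depots as exchanging lipids directly, a second variant adds
BAT↔iWAT, BAT↔eWAT and iWAT↔eWAT; the B/N2 split (below) is the only
output affected.  Networks are YAML configs validated on load (unknown
compartments and self-loops rejected, duplicate edges collapsed,
disconnection warned), and every run's metadata records the full network
definition and a digest of it.

## Presence rule

A variable is present in a (group, compartment) cell when
`#{replicates with signal > 0} / #{replicates in the cell} >= threshold`,
default 0.66.  Two consequences are deliberate: the denominator is per
group *and* compartment, so tissues with unequal replicate counts are
handled; and the comparison is `>=`, so 2 of 3 replicates (0.667) passes a
0.66 threshold.  Detection fractions are retained so that presence at any
other threshold can be re-derived without re-reading data; presence sets
are nested (monotone) in the threshold by construction, and a property
test asserts it.

## Traffic typing

Per group, every variable present somewhere receives exactly one type:
present in all compartments → **A**; exactly one → **U**; otherwise **B**
if any present pair of compartments is adjacent; else **N2** when exactly
two compartments, **Nk** when k ≥ 3.  Nk variables are reported
separately rather than forced into N2, which would corrupt counts.
Per-edge B lists contain every non-A variable present in both endpoints
(by construction these are exactly the edge's B variables); per-compartment
U lists contain that compartment's unique variables.  At system level each
B variable counts once however many edges it sits on.  A `legacy_b` mode
types every multi-compartment non-A variable as B — the behaviour before
the N2 type existed — as a sensitivity option.

The rule itself is ~20 lines (`classify_pattern`); an independent
brute-force restatement in the test suite checks it exhaustively on all
2^15 joint presence patterns of 3 species over a 5-compartment path
network, and planted-truth recovery checks it at full cohort scale.

## Group comparison

The two groups' typed lists are aligned per type, per edge and per
compartment into gained/lost lists ("lost" = in control, not exposed).
The comparison is exactly antisymmetric under swapping the groups, which
is asserted for every scope.  Per-class summaries reproduce the layout of
a published class-count table: total variables, then A/B/U/N2 per group.
Two "total" conventions are reported side by side (`total_detected`, all
variables in the input; `total_present`, the union of variables present in
either group) because published tables do not always say which they use.

## Jaccard–Tanimoto statistics

List similarity is J = |A∩B|/|A∪B|; J is undefined (an error, not 0/0)
when both lists are empty.  The p-value is a permutation estimate: both
memberships are resampled uniformly over the class's variable universe
preserving list sizes, and the observed J is located in the null J
distribution two-sidedly (both unusual dissimilarity and unusual
similarity count).  Because J is discrete at small list sizes, the default
estimator uses the smoothed Monte-Carlo CDF position — ties broken by a
seeded uniform draw — which makes the null distribution of p exactly
Uniform(0, 1); a Kolmogorov–Smirnov check over 500 null simulations
asserts the calibration.  A `conservative` option gives the classic
add-one permutation p instead.  All permutation work is vectorised and
deterministic given the seed.  The default 10 000 permutations resolve p
to ~1e-4; at least 1000 are recommended.

## Error-normalised fold change

ENFC = log10(x̄_E/x̄_C) / f(a, b) with group means x̄ and SDs a (exposed),
b (control).  Choices:

* **Error combination.** The source formula's typesetting is ambiguous, so
  the default is the literal reading f = (a²+b²)/2, with
  `rms` = sqrt((a²+b²)/2) and `root_sum_sq` = sqrt(a²+b²) selectable.
  Note the literal form has units of 1/variance on the raw scale, so its
  magnitudes depend on instrument units; the `rms`+`log10` combination is
  unit-invariant (asserted by a scale-invariance test) and is what the
  power sweep uses internally for comparability across effect sizes.
* **Error scale.** SDs default to the raw signal scale; `log10` takes SDs
  of log10 of the positive replicate values (matching the log-ratio
  numerator).
* **Zero handling.** No pseudocounts.  One zero mean → qualifier
  `zero-mean-control`/`zero-mean-exposed` with NaN value (direction
  implied); both zero → value 0 with qualifier `undefined`; zero or
  undefined combined error → `zero-error`.  Presence/absence questions
  belong to the switch analysis, not to imputation.
* **Targets.** Class totals sum replicate-level signals first, then take
  ENFC of the totals.  Subset ratios (e.g. essential-PUFA-containing
  species, default {FA(22:6), FA(22:5)}, against the rest of the class)
  form the per-replicate ratio first and take ENFC of the ratios;
  replicates with zero complement are excluded with a warning.
  Sum-resolution species, whose chains are unknown, fall in the
  complement.
* RADAR exports use one fixed compartment order (plasma, liver, heart,
  lung, kidney, small intestine, gastrocnemius, BAT, iWAT, eWAT, then any
  others) so plots are comparable across classes and runs.
* An optional normalisation column is not implemented; inputs are assumed
  already normalised consistently across samples, and the run metadata
  records the input digest instead.

ENFC is antisymmetric under group swap (including mirrored qualifiers),
and agrees with an independent replicate-level recomputation to 1e-12 on
fixtures and at cohort scale.

## Synthetic cohorts

The generator emulates the *structure* of a real multi-tissue cohort, not
its biology.  Defaults are the study's conditions: the 10-compartment
mouse network, groups "Room temp." and "Cold Exposed", 6 replicates per
group, and per-class planted A/B/U/N2 counts at the published scale (~921
species across AC, PC, PE, PG, PI, PS, SLs, TG).  Species names are drawn
from realistic acyl pools (even and odd chains, PUFAs, sphingoid bases; a
15 % fraction rendered at sum resolution), unique by identity.
Intensities are log-normal per species — log10 means uniform on [3, 6] to
create rank structure, within-group log10 SD 0.2, values typical of MS
peak intensities — identical across compartments and groups unless a fold
effect is planted.  Dropout zeroes a replicate's signal (the failure mode
the ">0" presence rule sees) within present cells; a dropout rate
exceeding 1 − threshold triggers a design warning because it risks
flipping presence calls.  Planted presence patterns are re-classified at
generation time and must reproduce their declared types, so the truth
object is consistent by construction; infeasible requests (N2 on a
complete graph, Nk with no independent set of size k, more species than
distinct names) are rejected with an explanation.

What passing these tests shows: the pipeline's logic is exact on data
satisfying its assumptions.  What it does not show: robustness to real MS
artefacts (isotope overlap, in-source fragmentation beyond the DG/TG
merge, batch effects, intensity-dependent missingness), which the
generator deliberately does not model.

`perturb_for_power` sweeps dropout rates (reporting type misclassification
against planted truth) and fold effects (reporting recovered class-total
ENFC under the unit-invariant error options), yielding a manifest for
power/threshold characterisation of the 0.66 rule.

## Problem sizes and determinism

The test suite and acceptance script run at deliberately chosen sizes:
full-scale cohorts (~920–1000 species, 110 k rows) for recovery and
antisymmetry checks, exhaustive 2^15-pattern enumeration for the
classifier oracle, 500 simulations × 999 permutations for p-value
calibration, 20 randomised designs for planted-type recovery.  Every
source of randomness flows from an explicit seed (numpy `default_rng`);
the same seed reproduces cohorts byte-for-byte and analyses exactly.

## Known limitations

* The published figure that motivated the default network does not
  enumerate its edges; results affected by the B/N2 split should be
  checked under both shipped variants.
* The permutation p-value treats the two lists as exchangeable random
  subsets of the universe; a closed-form alternative is not implemented
  (the permutation slot is the extension point).
* No significance testing on ENFC values; they are effect sizes relative
  to measurement error.
* No plotting: pie-chart and RADAR products are tidy CSVs for external
  plotting tools.
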