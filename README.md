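# lipidtraffic

Network-based **lipid traffic analysis** for multi-tissue lipidomics.

Lipidomics studies that profile many tissues of the same organism (plasma,
liver, heart, adipose depots, ...) can ask a question single-tissue studies
cannot: *how does the routing of lipids through the whole system change
between two phenotypes?*  This package implements that analysis for tidy
two-group abundance tables — for example a mouse cold-exposure cohort with
a control ("Room temp.") and a cold-exposed group — and is aimed at
lipidomics and systems-metabolism researchers.

## The method

The organism is modelled as a **compartment network**: tissues/fluids as
nodes, with undirected edges between compartments known to exchange lipids
(by default, plasma as the circulation hub connected to every tissue, plus
the small-intestine–liver portal edge; the network is an editable YAML
config).

**Switch analysis.** A lipid variable is *present* in a (group, compartment)
cell when its signal is > 0 in ≥ 66 % of that cell's replicates (threshold
configurable).  Each variable present somewhere is then typed, per group:

* **A** — present in every compartment ("found throughout the system");
* **B** — present in both ends of at least one network edge;
* **U** — present in exactly one compartment;
* **N2** — present in exactly two *non-adjacent* compartments
  (**Nk**, k ≥ 3, analogously, reported separately).

Aligning the two groups' typed lists per class, per edge and per
compartment yields the switch report: which variables were gained or lost,
and where.  List similarity is summarised by the Jaccard–Tanimoto
coefficient *J* = |A∩B|/|A∪B| with a seeded permutation *p*-value
(memberships resampled over the variable universe preserving list sizes,
two-sided on dissimilarity).

**Abundance analysis.** Quantitative change is measured by the
error-normalised fold change between exposed (E) and control (C) groups,

```
ENFC = log10(x̄_E / x̄_C) / f(a, b)
```

with group SDs *a*, *b* and error combination *f(a,b) = (a²+b²)/2* by
default (`rms` and `root_sum_sq` forms, and log10-scale SDs, are options).
ENFC is computed per class total, per named species and for
subset/complement ratios (e.g. essential-PUFA-containing TGs — FA(22:6)
DHA, FA(22:5) DPA — against all other TGs), per compartment, exported as
RADAR-ready tables.

A **synthetic cohort generator** plants known traffic types, presence
switches and fold effects at the scale of the real study (10 compartments,
~920 species over 8 classes, 6 replicates/group), so every stage is tested
against ground truth.

## Worked example

```python
import lipidtraffic as lt

design = lt.SyntheticDesign(
    class_counts={"TG": {"A": 3, "B": 5, "U": 5, "N2": 3}},
    effects=(lt.FoldEffect("TG", "heart", 0.5),),   # halve heart TG on exposure
    seed=42,
)
table, truth = lt.generate_cohort(design)

est = lt.SwitchAnalysis(n_perm=1000, seed=0).fit(table)
print(est.counts_)
```

```
       total_detected  total_present  ...  A (Room temp.)  B (Room temp.)  U (Room temp.)  N2 (Room temp.)
class
TG                 16             16  ...               3               5               5                3
```

The classifier recovers exactly the planted 3/5/5/3 A/B/U/N2 design in
both groups, and the per-class system comparison gives `J = 1.0,
p = 0.12`: identical lists, as planted (no presence switch was planted, so
a *J* of 1 with an unremarkable *p* is the correct null answer).

```python
enfc = lt.EnfcAnalysis(error_form="rms", error_scale="log10").fit(table)
print(enfc.class_totals_[["class", "compartment", "enfc", "qualifier"]])
```

```
class     compartment      enfc qualifier
   TG          plasma  0.239342   defined
   TG           liver -1.048107   defined
   TG           heart -1.962368   defined
   ...
```

The planted halving shows up as the strongest negative ENFC in the heart
(expected ≈ −log10 2 / 0.2 ≈ −1.5 under the rms/log10 error options with
the generator's 0.2 log10-SD; other compartments fluctuate within the
noise of 6 replicates).

The same analyses run from the shell:

```sh
lta simulate --out sim --seed 42
lta switch    --input sim/cohort.csv --out switch_run --seed 0
lta abundance --input sim/cohort.csv --out enfc_run --ratio-class TG
lta report    --input sim/cohort.csv --out full_run
```

Every run directory carries `run_metadata.json` (version, configuration,
network definition and hash, input digest, seed); identical inputs and
seeds give byte-identical outputs.

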