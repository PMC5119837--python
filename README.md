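# mutpanel

Hotspot-panel design and driver-gene profiling for somatic mutation cohorts.

Targeted assays for circulating tumour DNA (droplet digital PCR, SNV arrays)
interrogate *specific genomic positions*, not whole genes. Designing an
"off-the-shelf" assay for a heterogeneous cancer therefore comes down to a
population question: which recurrently mutated loci ("hotspots"), and how
many of them, are needed to cover most patients in a clinical population?
`mutpanel` answers this from standard Mutation Annotation Format (MAF) input:
it collapses called somatic mutations into loci keyed by gene and genomic
start, ranks loci by patient prevalence, builds fixed-size panels, quantifies
patient coverage at multiple depths, validates a panel on an independent
cohort, and profiles driver-gene alteration patterns (coverage, burden
ordering, mutual exclusivity, protein-position hotspots). A ground-truthed
synthetic-cohort generator makes every stage testable without
controlled-access data.

## Definitions

For a cohort with sample universe *S* (|*S*| = *n*, possibly including
mutation-free patients):

- **locus** — a distinct (gene, chromosome, start) among eligible
  (non-synonymous, by default) records; all alt alleles at one start collapse.
- **prevalence** of locus *ℓ* — |{patients with ≥1 mutation at *ℓ*}| / *n*.
- **panel** of size *k* — the top *k* loci by prevalence (ties broken
  lexicographically, so panels are deterministic).
- **depth** of patient *p* — the number of distinct panel loci at which *p*
  is mutated.
- **coverage at depth d** — fraction of *S* with depth ≥ *d*.

Driver-gene analysis maps mutation classes to alteration classes
(nonsense/frameshift/splice → TRUNCATING, in-frame indels → INFRAME,
missense → MISSENSE) and discrete copy-number calls to AMP (+2) / DEEP_DEL
(−2); pairwise association between genes uses a two-sided Fisher exact test
with Benjamini–Hochberg correction across pairs and a Haldane–Anscombe
continuity-corrected odds ratio.

## Worked example

Simulate a 519-patient lung-adenocarcinoma-like discovery cohort (ten
planted hotspots at 3–15% prevalence over a 20,000-locus passenger tail),
build the top-400 panel, and validate it on an independent 183-patient
cohort drawn from the same population:

```python
from mutpanel import (
    lung_cohort_spec, generate_cohort, aggregate_loci, rank_loci,
    build_panel, coverage_profile, apply_panel,
)

cohort, truth = generate_cohort(lung_cohort_spec(519, seed=11, name="discovery"))
ranked = rank_loci(aggregate_loci(cohort))            # 3831 distinct loci
panel = build_panel(ranked, 400, source_cohort="discovery")
prof = coverage_profile(panel, cohort, depths=[1, 2, 5, 10])

validation, _ = generate_cohort(lung_cohort_spec(183, seed=12, name="validation"))
report = apply_panel(panel, validation, depths=[1])
```

Output for these seeds:

```
records: 4701  samples: 519
  KRAS_25398285   prevalence 0.146 (76 patients)   <- planted at 0.150
  TP53_7578406    prevalence 0.081 (42 patients)   <- planted at 0.100
coverage at depth >= 1: 0.813
coverage at depth >= 2: 0.553
coverage at depth >= 5: 0.158
depth per patient: mean 2.45, median 2.0, sd 2.52
validation coverage at depth >= 1: 0.678
panel loci absent from validation: 362
```

Reading this: the planted hotspots are recovered at the top of the ranking
at their generating prevalences; a 400-locus panel covers 81% of the
discovery cohort at depth ≥1 but only 68% of an independent cohort — the
drop is real, not a bug: beyond the shared hotspots, the panel's tail is
filled with discovery-specific passenger loci that do not recur in new
patients (362 of 400 panel loci are never mutated in the validation cohort),
which is exactly why frequency-ranked hotspot panels overfit their discovery
dataset.

The same pipeline runs from a shell on any MAF:

```sh
mutpanel simulate --n 519 --seed 11 --out sim/
mutpanel panel --maf sim/cohort.maf --samples sim/samples.txt --size 400 --out panel.tsv
mutpanel validate --panel-maf sim/cohort.maf --maf other_cohort.maf --out report.tsv
mutpanel drivers --maf sim/cohort.maf --out-prefix drivers
```

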