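# Methods

## Input model and the sample universe

All statistics are patient-level fractions, so the denominator matters more
than any single parser decision. A `Cohort` couples MAF records with an
explicit *sample universe*: by default the distinct tumour barcodes in the
MAF, optionally an explicit sample list that may include mutation-free
patients. A MAF alone cannot reveal mutation-free patients; when a clinical
sample list exists it is the correct denominator and supplying it can only
shrink prevalences, never grow them. Coordinates stay 1-based inclusive
end-to-end (the MAF convention), chromosome names are normalised by
stripping `chr` and folding `23`/`24` onto `X`/`Y`, and duplicate rows
(identical sample, span and alleles) are dropped with a logged count so a
twice-reported mutation cannot double a patient's depth.

Silent (synonymous) mutations are parsed and retained but excluded from
hotspot ranking, panels and driver alterations by default — a panel targets
functional, non-synonymous events — with `include_silent=True` available
everywhere. Classification strings outside the documented mapping table
classify as OTHER with a warning rather than failing: TCGA-era MAFs are not
clean enough to make unknown categories fatal.

## Locus model

A locus is keyed by (gene symbol, chromosome, start). Collapsing alt
alleles at one start matches how recurrently mutated positions behave
biologically (a codon-12 hotspot is one assay target with several alternate
alleles) and how such loci are annotated (`KRAS_25398285`). A strict mode
keys on (gene, chromosome, start, ref, alt) for allele-resolved work.
Indels are keyed by their MAF start like SNVs; no window or codon merging is
attempted — nearby starts stay distinct loci, which makes the ranking
conservative about recurrence.

"Scored based on frequency" is implemented as patient prevalence: the
fraction of the universe with ≥1 eligible mutation at the locus, each
patient counted once. Raw mutation counts would over-weight hypermutated
patients; every downstream metric is a fraction of patients, so the score is
too. Ranking is descending prevalence with the tie-break
(gene, chromosome, start) ascending — a total order, so panels are
reproducible run to run and invariant to record order.

## Panels, coverage and depth

`build_panel(ranked, k)` is a pure prefix: panel membership is purely
frequency-ranked, deliberately not a greedy set-cover (which would optimise
marginal coverage but break the interpretation of the panel as "the k most
recurrent loci"). Depth counts *distinct* panel loci per patient by default
because a locus-targeted assay scores a locus once; `count_records=True`
switches to row counting for comparison with per-mutation bookkeeping. Both
the median and the mean of the depth distribution are reported side by side
(summaries of this skewed distribution differ noticeably, and published
figures have used both words for the same number). The default depth
thresholds {1, 2, 5, 10} cover the assay-relevant range; standard deviation
defaults to the sample (n−1) form with a population flag.

`coverage_curve` computes coverage over a (k, d) grid incrementally —
walking down the ranking and raising the depth of each locus's patient set —
which is algebraically identical to rebuilding each top-k panel but linear
in total patient-set size. The test suite pins both paths to a brute-force
per-patient scan.

Panel composition classifies each locus by its modal variant type (ties
resolved SNV > INS > DEL, biasing toward the type an SNV-oriented assay
would target) and tallies the substitution spectrum over SNV records at
panel loci, as 12 directional classes or 6 pyrimidine-reference classes
behind a flag.

## Cross-cohort validation

A panel is applied to a validation cohort by exact key match on
(gene, chromosome, start); no liftover and no tolerance window. Keeping the
gene in the key guards against coordinate collisions across annotation
versions; `match_on_position=True` drops it. Because a build mismatch is
indistinguishable from genuine non-recurrence at the data level, a heuristic
warning fires when >90% of panel loci are absent from the validation cohort.
Note that a large frequency-ranked panel on a modest validation cohort can
trip this warning legitimately: the panel tail is discovery-specific
passenger loci that simply do not recur. Per-locus prevalences are
recomputed from each cohort with that cohort's own denominator.

## Driver-gene analysis

The alteration matrix binarises biology into five classes per (patient,
gene) cell: TRUNCATING (nonsense, frameshift, splice), INFRAME, MISSENSE,
and from discrete copy-number calls AMP (+2) and DEEP_DEL (−2). Shallow
calls (±1) are excluded by default, following the cBioPortal convention that
single-copy events are unreliable alteration evidence; a flag includes them.
Burden counts altered *genes*, so a missense + amplification in one gene is
one unit — matching waterfall-plot column semantics. The waterfall order is
descending burden with sample-id tie-break.

Pairwise association uses the two-sided Fisher exact test (scipy) on the
2×2 altered/not table per unordered gene pair, Benjamini–Hochberg correction
across all pairs (statsmodels), and a log odds ratio with Haldane–Anscombe
+0.5 on all cells whenever any cell is zero. Direction (co-occurrence vs
mutual exclusivity) requires q < α and an odds ratio off 1. A gene altered
in zero or all patients has no defined association; such pairs are emitted
with p = 1 and a degenerate flag rather than dropped, so pair lists keep a
fixed shape. The exact test is intentionally conservative: its true size at
α = 0.05 in the planted null scenario used by the tests (n = 200, two
independent genes at prevalence 0.3) is 0.041, not 0.050 — a property of
discreteness, not an implementation artefact.

The default 23-gene list (14 oncogenes, 9 suppressors) reflects canonical
lung-adenocarcinoma drivers and is a configuration default, not a modelling
assumption; YAML gene lists override it entirely.

Protein-position tallies parse the first residue number from HGVS-style
short protein changes (`p.G12D`, `p.E746_A750del`, `p.Q61*`, `p.F507fs`)
and classify by the record's variant classification rather than re-deriving
the consequence from the string. Unparseable or non-coding records land in
an explicit unmapped bucket — never silently dropped — and the top-position
report expresses the busiest residue as a fraction of the gene's SNVs.

## Synthetic cohorts

The generator emulates the population structure the pipeline exists to
analyse: a small set of true hotspots, each carried independently by a
patient with its prevalence; a long passenger tail (loci drawn uniformly
without replacement from a large synthetic space, so each passenger locus
has expected prevalence mean/L); an overdispersed per-patient passenger
burden, negative-binomial with mean 8 and dispersion 0.5 by default to
reproduce the heavy-tailed burden seen in real waterfall plots; a
configurable substitution spectrum and indel fraction; and planted pairwise
association, drawn per patient from the exact 2×2 joint distribution with
the requested margins and odds ratio (solved in closed form — the quadratic
in p11 — so no rejection sampling). For strictly interior margins every
positive odds ratio is feasible; the hard-error path covers degenerate
margins and non-positive odds ratios. All randomness derives from one
integer seed, and identical seeds give byte-identical MAF output.

The bundled lung-like template (`lung_cohort_spec`) plants ten hotspots
spanning 0.03–0.15 prevalence (0.15 for the KRAS-codon-12-like locus, with
intermediate values including 0.052 and 0.042 for the IL32-/RPSA-like
loci), a 20,000-locus passenger space, a uniform substitution spectrum, a
10% indel fraction, and one mutually exclusive (OR 0.25) plus one
co-occurring (OR 3) driver pair. These values were fixed once as a
realistic landscape for this disease.

What the generator does **not** emulate: sequence-context mutational
signatures, gene length and regional mutation-rate variation, subclonality,
caller/filter artefacts, and inter-cohort batch differences. Passing tests
therefore demonstrate the *statistical machinery* — aggregation, ranking,
coverage, association — is correct under a controlled landscape; they do
not certify any particular real-data panel, whose content depends on the
MAF freeze and calling pipeline. Cross-cohort behaviour of the synthetic
template is qualitatively faithful, though: a 400-locus panel covers ~81%
of its own 519-patient discovery cohort at depth ≥1 but only ~68% of an
independent 183-patient cohort, because the panel tail is populated by
discovery-specific passenger singletons.

## Numerical and scale choices

Fisher p-values are exact; the test suite checks them against an exhaustive
fixed-margins enumeration in exact integer arithmetic on every 2×2 table
with n ≤ 40, and type-I error by 2000-replicate simulation. Planted-hotspot
recovery uses 20 replicate cohorts of 1000 patients with hotspots at
{0.15, 0.10, 0.08, 0.05} over a 4000-locus passenger tail (expected
passenger prevalence 0.002), sized so the maximum passenger order statistic
sits well below the weakest hotspot. Coverage oracle equivalence runs over
200 randomly parameterised cohorts of ≤10⁴ records. The acceptance script
uses discovery/validation sizes of 519/183 patients. These sizes keep the
whole suite fast while leaving each check's statistical resolution ample.

Fractions reported as percentages are percentages of the sample universe;
every tolerance in the tests is either exact (oracle equivalence, hand
counts) or an explicit probabilistic interval (exact binomial or Wald CI at
a stated level).

## Known limitations

- No significance model for recurrence (no background mutation-rate model);
  prevalence ranking will promote passengers in hypermutated cohorts.
- No window/codon merging: adjacent starts within one codon are separate
  loci, which can split a biological hotspot across panel entries.
- Cross-cohort matching is exact-coordinate; cohorts on different genome
  builds must be lifted over upstream.
- Copy-number calls are consumed as given; no calling, segmentation or
  thresholding is performed.
- The pairwise association test conditions on margins and tests each pair
  marginally; it is not a set-level exclusivity model.
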