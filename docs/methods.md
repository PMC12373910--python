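# Methods

This note records the models behind `phagescreen`, the parameters that
matter, the choices made where the design was genuinely open, and what
the synthetic-data generators do and do not emulate.

## Read model and barcode matching

An amplicon read is `prefix + up_flank + barcode + down_context
[+ tag + insertion site]`. Three dialects are built in
(`phagescreen.layouts`):

| dialect | prefix | up flank / budget | barcode | down context / budget | extras |
|---|---|---|---|---|---|
| AG | 5–7 random nt | 20 bp / 0 | 10 bp | 20 bp / 0 | — |
| Tn5 mapping | none | 23 bp / ≤ 3 | 20 bp | 50 bp / ≤ 6 | 4 nt tag + 16–50 nt IS |
| Tn5 BarSeq | none | 18 bp / ≤ 3 | 20 bp | 18 bp / ≤ 4 | — |

All comparisons are Hamming distances; `N` counts as a mismatch
(conservative — an uncalled base never helps a flank pass). Candidate
prefix offsets are scanned in ascending order and the first placement
satisfying both budgets wins; the staggered prefixes make multiple
acceptable placements vanishingly unlikely in practice, but a
deterministic tie-break removes the ambiguity. On failure a read
reports the furthest stage it reached (`FLANK_UP` < `FLANK_DOWN`), and
reads with characters outside `ACGTN` are `MALFORMED`. Whitelist
matching is exact, with no error correction toward the nearest
barcode: libraries are generated with pairwise Hamming distance ≥ 3,
so a single substitution can never cross-assign, and a substitution
inside the barcode simply lands in the audited
`rejected_unknown_barcode` class. A vectorized batch extractor is
property-tested to agree read-for-read with the scalar reference
implementation.

## Fitness scores and hit calling

Scores are `log2((count + 1) / median(count + 1))` per sample; the
median over library members represents neutral fitness in a pooled
screen. The +1 pseudocount is a choice the procedure itself leaves
open: it keeps fully depleted members finite while shifting the median
by < 0.1% at realistic depths (≥ 10³ reads/member).

Representation filters: `LOW_READS` if a member has < 100 reads
(exactly 100 passes — "cutoff of 100" is read as the minimum
acceptable), and `MAD_OUTLIER` if its mean score across replicates
falls more than 3 *unscaled* MADs (no 1.4826 consistency factor) below
the median of those means. Both hit-blocking filters are evaluated on
the *pre-infection* samples (baseline and uninfected) by default:
candidates must be well represented to begin with, while depletion in
the infected samples is the signal being measured — flagging it would
veto every true hit. The MAD condition set is switchable
(`mad_condition`, `low_read_conditions`).

Effects: `delta_inf = mean(f_infected) − mean(f_uninfected)` and
`delta_host = mean(f_uninfected) − mean(f_baseline)`. Reproducibility
is a paired t-test on per-replicate differences (df = n − 1); whether
the original analysis paired replicates is not stated, so the
two-sample alternative is available (`paired=False`). Zero-variance
conventions: all-zero differences give p = 1 (no evidence of change);
identical *nonzero* differences are flagged `DEGENERATE` with p = NaN
rather than manufacturing p = 0 from degenerate data. Hits require no
flags, p ≤ 0.2 and |delta_inf| ≥ log2(4) = 2, in either direction
(negative = sensitizing, positive = protective). A
Benjamini–Hochberg column is emitted for information only; the gate is
the raw P, which the procedure uses as a reproducibility filter, not
an FDR control. The same machinery runs the Tn5 gene-depletion screens
with two replicates (df = 1).

## Tn5 insertion mapping

Fragments are distinct `(barcode, tag, IS)` triples; PCR-duplicate
collapse keeps one representative per triple. Localization is by
unique exact substring match against the host genome — a deliberate
replacement for read alignment, made sound by the generator's
guarantee that every insertion's downstream 50-mer is unique (each
emitted IS segment is additionally lengthened until it matches
uniquely). An IS matching the donor vector is `VECTOR`; an absent or
multi-mapping IS is `UNLOCATED`.

Dominance rule: a barcode is retained iff its modal genome position
accounts for strictly more than 90% of fragments ("over 90%" — 0.90
exactly is discarded, tested at the boundary). Two denominator
choices were open. `VECTOR` fragments count toward the denominator
(they are real molecules carrying that barcode; a flag exposes the
alternative). `UNLOCATED` fragments are *excluded*: under exact-match
localization they correspond to alignment-stage unmapped reads, which
the original procedure discards before the dominance rule — counting
them would let ordinary IS sequencing errors (an error anywhere in a
16–50 nt segment voids an exact match) discard genuinely unambiguous
barcodes wholesale.

Gene assignment is containment of the insertion coordinate in the
annotated `[start, end]` interval (1-based inclusive everywhere);
strand is ignored; positions outside every gene pool under
`INTERGENIC`. Gene counts conserve mass: mapped + discarded + unknown
barcode counts equal the per-sample total.

## AP-MS enrichment

Quantile normalization is applied jointly over the six samples of a
host (bait triplicate ∪ control triplicate): the simplest reading of
normalizing a test set "against" a control set; a map-onto-control
mode could be added behind the same interface but is not currently
exposed. Ties within a sample receive the mean of the tied ranks'
means. Zeros (unobserved proteins) participate as the smallest values,
keeping the protein universe constant. Fold change uses a floor of
half the smallest positive normalized value on both means so absent
proteins yield large-but-finite fold changes; the t-test is a
two-sample Student t (df = 4 with triplicates).

Summed ranks: within each host, proteins with FC > 0 are ranked
descending by FC; a protein outside a host's positive set contributes
that host's worst positive rank + 1 — how such proteins enter the
cross-host sum is unstated in the source procedure, and this
convention keeps summed ranks comparable across proteins while
penalizing inconsistency.

## Apparent MOI

`MOI_a = −ln(surviving fraction)` — the Poisson zero class under the
assumption that every infected cell dies. (The source Methods display
an equation reading `−ln(MOI_e)`; its own surrounding prose defines
the zero class on the surviving fraction, so the displayed form is
treated as a typographical slip and the prose definition is
implemented.) Zero-survivor rows raise an error directing the caller
to an explicit floor (e.g. 0.5/n_cells) rather than being silently
substituted, since −ln 0 is undefined and a saturated assay should be
visible. The slope of `MOI_a = m·MOI_e` is ordinary least squares
through the origin, `m = Σ(e·a)/Σ(e²)` (no fitting method is named in
the source; OLS-through-origin is the canonical reading);
`fold_reduction = 1/m` exactly. `plan_inoculum` converts a target
apparent MOI into a lysate volume via `MOI_e = target × fold_reduction`.

## Synthetic-data generators

All generators are pure functions of (parameters, seed) — byte-identical
on re-run — and ship truth sidecars that downstream code never reads
except in test assertions.

* **Abundance model.** Baseline member proportions are log2-uniform on
  [−1, 1] (≤ 4-fold spread), modelling a pooled library that passed
  evenness QC. The bounded, light-tailed form matters: for any
  approximately normal abundance spread, ~2.2% of members sit below
  median − 3·MAD *by construction* (3 unscaled MADs ≈ 2.0 σ), so the
  MAD filter would flag random healthy members in every screen; with a
  bounded spread the filter fires only on genuine dropouts, which is
  its purpose.
* **Counts.** Each sample is one multinomial draw of `depth` reads;
  infected samples re-weight abundances by `2^effect` and renormalize.
  Totals equal the requested depth exactly.
* **Reads.** Substitution-only errors (no indels): the matching rules
  are Hamming-based, so indels would only inflate the reject class.
  A substitution always changes the base. Quality strings are a
  constant placeholder; nothing downstream consumes quality.
* **Tn5 reference.** Random genome, non-overlapping genes (one per
  equal slot at a random offset), uniformly placed insertions redrawn
  until each downstream 50-mer is unique. Fragments get random tags,
  redrawn on the rare triple collision so genuine fragments are
  distinct molecules and only `dup_rate` produces duplicates;
  `chimera_rate` swaps in a wrong insertion's IS.
* **AP-MS.** Per-protein log-normal baselines (log2 mean 20, sd 2),
  replicate noise log-normal at a given CV, spiked interactors
  multiplied by `2^effect` in bait samples. Recovery simulations use
  500 proteins and CV 0.2, a typical label-free scale.
* **MOI.** Survivors ~ Binomial(n_cells, exp(−MOI_e/k)).

What the generators do **not** emulate — and hence what passing tests
do not show about real data: sequencing-quality variation, indels,
adapter read-through, paired-end structure, index hopping, PCR
amplification bias, strain fitness differences unrelated to infection,
batch effects between replicates, missing-not-at-random proteomics
dropout (a missing-at-random option exists, default off), and real
genome repeat structure (localization is guaranteed unambiguous by
construction).

## Problem sizes and numerics

The test and acceptance runs use the screens' study-scale conditions
where they are what is being demonstrated (200-member AG library,
depth 10⁶, 3 replicates, 10 members at 16-fold depletion; adsorption
factor 26 with 10⁶ cells) and compact versions elsewhere (20 kb
genomes with 200 insertions, BarSeq depth 3×10⁵ with 2 replicates,
500-protein matrices) — sizes chosen so every recovery property is
comfortably identifiable. Replication: 20 seeds for screen and MOI
recovery, 100 for AP-MS rank recovery. Tolerances: closed-form
identities are checked to machine precision; stochastic recoveries at
the bounds stated in the tests (e.g. fold reduction within 5%).
Determinism of the pipelines is verified byte-for-byte, which is why
output tables use fixed float formatting and manifests contain no
timestamps.

## Known limitations

* Exact-match localization requires the uniqueness guarantee; on a real
  genome with repeats an aligner-based `locate` would be needed.
* Gene-level depletion does not model insertion position within the
  gene (no central-fraction trimming) or essentiality from insertion
  density.
* The AG hit gate inherits the procedure's raw-P reproducibility
  filter; with two replicates (Tn5 mode) the t-test has a single
  degree of freedom and P-values are coarse — the fold-change gate
  does most of the work there.
* `concordance` excludes zero-proportion members from the log-scale
  statistic; libraries with many dropouts should examine the reported
  exclusion count.
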