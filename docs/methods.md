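# Methods

This note documents the statistical model behind `bioidkit`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical corner cases. Nothing here reports a result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Quantification model

Input is a long-format precursor table: one row per (sample, protein group,
modified peptide, charge) with a linear-scale intensity. The chain to a
protein-level log2 matrix is:

1. **Global median normalization.** Each sample's intensities are scaled by
   a constant so its median log2 intensity equals the grand mean of the
   pre-normalization per-sample medians (equalized within 1e-9). This
   assumes most proteins are unchanged between samples; in a pulldown where
   a sizable fraction of proteins is genuinely enriched on the bait side,
   the correction deliberately shifts the bait samples down, which
   attenuates measured fold changes by a few tenths of a log2 unit. This
   is inherent to median normalization, not a defect, and the tests that
   check generator calibration therefore assert raw-matrix properties.
2. **Precursor filtering.** The weakest `fraction` (default 0.2) of
   precursors by cross-sample median intensity is removed globally — a
   rank-based reading of lower-percentile intensity filtering; `fraction=0`
   is the identity and `fraction=1` empties the table. Ties are broken by
   the precursor key so the operation is deterministic.
3. **Top-3 roll-up.** Per (protein, sample), the value is the mean log2
   intensity of the protein's three strongest precursors (by cross-sample
   median; fewer if the protein has fewer). This is a transparent stand-in
   for proprietary search-engine LFQ summarization; it is shift-equivariant
   and easy to verify by hand. Proteins supported by exactly one precursor
   overall ("single hits") are excluded and reported — one-peptide
   identifications are not trusted for quantification.
4. **Left-censored global imputation.** Missing values are drawn from a
   Gaussian centered at the global 1st percentile of observed log2 values
   with sd 0.3 (both configurable). This mimics intensities censored at
   the detection limit. Observed values are never modified, the draw order
   is fixed row-major, and a seed fully determines the result. At least 20
   observed values are required to estimate the placement.

Replicate reproducibility is summarized by the coefficient of variation,
CV = sd/mean (ddof = 1) on the **linear** scale — the standard MS QC
convention — requiring ≥ 2 observed values per group; CV is scale-invariant
and zero for constant replicates.

## Differential testing

The bait-vs-control contrast is a two-sided Welch unequal-variance t-test
per protein on log2 values, with Benjamini–Hochberg adjustment across all
tested proteins reported as the Q-value. Welch was chosen because it is
assumption-light (no equal-variance requirement, robust at n = 4 + 4) and
its type-I behavior is easy to audit: on a null simulation (1000 proteins,
zero effects) the p < 0.05 fraction sits within three binomial standard
errors of 0.05 and BH makes no discoveries (both checked in the acceptance
suite). Proteins with fewer than two observed values on a side are skipped
and reported rather than tested; degenerate zero-variance cases return
p = 1 when the means agree and p = 0 when they differ. Group-level
distribution comparisons use the Wilcoxon rank-sum test (exact null
enumeration when both groups have n ≤ 8 and no ties, otherwise the normal
approximation with tie correction) or one-way ANOVA; a design with no
variance anywhere returns F = 0, p = 1.

## Interactor scoring and classification

The enrichment score is the sum of two min–max-scaled components,
`minmax(−log10 Q) + minmax(avg log2 ratio)`, each oriented so larger means
more enriched; the weighting is configurable (`score_weights`). This
realization satisfies the intended semantics — strictly monotone in each
component with the other fixed, bounded in [0, 2], and equal to 2 exactly
for a protein carrying both the smallest Q and the largest ratio. When all
proteins tie on a component (scaling degeneracy) that component contributes
0.5 to everyone. Q-values of exactly zero are clamped to the smallest
positive Q in the table and logged. Ranks are assigned by descending
score with deterministic tie-breaking (smaller Q, then accession).

The classifier is a univariate, unregularized logistic regression of the
TP/TN label on the score, fit on labeled proteins only (≥ 3 per class);
unlabeled proteins are scored and ranked but never enter fitting or
evaluation. Because the link is monotone, ranking by probability equals
ranking by score whenever the coefficient is positive. Complete separation
yields a large finite coefficient; the cutoff never depends on convergence
because it is computed from the scores directly:

* **FPR cutoff** — the smallest *observed* score `c` with
  `|TN ≥ c| / |TN| < α` (default α = 0.05; no interpolation between
  observed scores). If no observed score qualifies the cutoff is +∞,
  nothing is called enriched, and a warning is logged. `α ≥ 1` is treated
  as the explicit degenerate boundary "everything passes" and returns the
  minimum observed score (a strict reading would make the bound
  unsatisfiable at the minimum, where the TN rate is 1 by construction).
* **F1 report** — precision `TP≥c / (TP≥c + TN≥c)`, recall `TP≥c / |TP|`,
  evaluated on labeled proteins only; an empty call set is flagged and
  scores F1 = 0.

TopN recovery counts members of each annotation set among the top-N ranks
(N clamped to the number of ranked proteins, with a warning), and the
interactor fraction is `100·|known ∩ candidates| / |candidates|` reported
to one decimal.

The curated label sets follow the proteasome-bait design: positives are
proteasome subunits and associated proteins **minus the 19S lid members**
(lid subunits are not close enough to the 20S bait for direct
biotinylation after freeze-induced disassembly, so keeping them would
penalize every method equally and bias the evaluation); negatives are
naturally biotinylated mitochondrial proteins, which carry biotin
regardless of the ligase and therefore calibrate the unspecific-enrichment
axis. Label sets must be disjoint after the lid exclusion; protein groups
join annotation lists via their leading accession.

## Biotinylation sites

`Biotin_K`-carrying precursors are parsed under a bracketed
modified-peptide grammar (flanking underscores optional, residues A–Z,
each optionally followed by `[ModName]`; `Biotin_K` on a non-lysine is a
hard error because it signals a corrupted report). Site coordinates are
1-based protein positions: peptide start + offset. One site is emitted per
distinct (protein, lysine position); per-sample intensity is the maximum
over covering precursors (robust to charge-state duplication; `sum` is
available behind a switch) and the best peptide is the covering peptide
with the highest median intensity. Site-level differential testing reuses
the protein engine verbatim on a sites × samples matrix — one engine, two
levels. The site-vs-protein fold-change concordance joins only sites whose
parent protein was quantified in the protein-level (first-elution)
contrast and refuses to report a correlation below three pairs.

## Substrate calling

With the proteasome inhibitor MG132 trapping substrates at the proteasome,
a candidate substrate must be enriched in the bait-vs-control contrast
under MG132 (log2 fold change > 1.5 and Q < 0.05 by default) and **not**
enriched under vehicle — implemented as the negation `NOT (fc > t AND
q < t_q)` of the same thresholds, the reading we consider intended for
"not with the vehicle control"; the alternative literal reading
(`fc < t AND q < t_q`) would demand significant *non*-enrichment and make
almost nothing a candidate. The two contrasts are outer-joined; a protein
missing from one side is treated as not enriched there and flagged.
Candidates that MG132 also significantly upregulates in the whole-cell
proteome (same thresholds, configurable) are demoted — their pulldown
enrichment is explained by abundance alone. Raising the fold-change
threshold or lowering the Q threshold can only shrink the candidate set.

## The synthetic-data generator

The generator emulates the statistical structure of a four-replicate
bait-vs-control DIA pulldown with planted truth; all randomness flows from
one seeded `numpy` generator and identical configurations serialize
byte-identically.

* **Abundance and noise.** Protein log2 abundance ~ N(25, 1.5). Replicate
  noise is log-normal with group-specific CVs (defaults: bait 0.15,
  control 0.25 — the control/ligase-only samples are noisier in practice
  because a larger share of their signal is unspecific binding), applied as
  a shared per-(protein, sample) log2 deviation of sd √ln(1+CV²)/ln 2 plus
  small per-precursor noise (sd 0.1). Each protein gets 2–6 precursors
  with N(0, 1) response offsets; one protein per class is forced to a
  single precursor so the single-hit filter is always exercised.
* **Classes.** True positives carry log2 effects drawn uniformly from
  (2, 6); true negatives have zero effect and equal abundance; a few "lid"
  proteins sit in the positive annotation list but have zero effect
  (exercising the lid exclusion); bystander background proteins appear at
  abundance scaled by `background_binding` and vanish from the report when
  it is 0.
* **Unspecific carry-over.** `background_binding` also adds a linear-scale
  floor (binding level × a fixed 2% carry-over fraction of cellular
  abundance) to the control side of enriched proteins. This compresses
  large apparent fold changes the way unspecific bead binding does, so
  raising the binding level degrades TP/TN separation — the median F1
  across seeds is nonincreasing in `background_binding` (checked in the
  acceptance suite). Ground truth stores the *specific* effect, i.e. the
  bait-vs-control difference before carry-over; with the binding level at
  0 the realized difference equals it exactly, which is how the
  null-calibration scenarios are constructed.
* **Missingness.** Missing-not-at-random: the lowest `missing_rate`
  quantile (default 5%) of all generated log2 values is censored, i.e.
  those rows are absent from the report, mimicking intensity-dependent DIA
  dropout.
* **Biotin sites.** Half of the true positives (configurable) carry 1–3
  biotinylated-lysine peptides whose intensities follow the parent
  protein's group means, so site-level fold changes track protein-level
  ones (r > 0.7 at default noise, checked).
* **Substrate scenario.** Three reports over one protein universe: MG132
  (substrates and confounders enriched, stable TP interactors enriched),
  vehicle (only TP enriched — substrates are null, so the vehicle
  exclusion removes stable interactors from the calls), and a whole-cell
  proteome MG132-vs-vehicle report in which only confounders
  (`confounder_fraction` of the substrate count, as extra planted
  proteins) are upregulated.

**What passing tests do and do not show.** The generator captures the
moments that drive the downstream statistics (group means, CV structure,
censoring, precursor multiplicity) but not retention-time structure,
interference, ratio compression from co-fragmentation, search-engine FDR,
shared peptides across protein groups, or realistic intensity
distributions (the empirical distribution of real data is not published;
these defaults are plausible, not fitted). Recovery rates on synthetic
data therefore bound what the code does under its own model, not what any
instrument achieves.

**A known, intended interaction.** Low-abundance proteins with strong
enrichment can have *all* control-side values censored and subsequently
imputed at the global 1st percentile; their measured fold change then
reflects (bait − imputation floor) rather than the planted effect and can
fall below the 1.5 substrate threshold. This fold-change compression at
the detection limit is exactly what left-censored global imputation does
to real DIA data; it is why substrate recall on generator defaults sits
near, rather than far above, the 90% mark.

## Orchestration

`run_pipeline` executes generate → ingest → quantify → differential →
classify → biotin_sites → substrates → qc, serializing every stage's
inputs and outputs into a run directory with a manifest (config hash,
seed, per-stage record counts, SHA-256 of every output file). Stage
failures leave partial outputs plus a `FAILED` marker naming the stage.
Reruns with the same config and seed are byte-identical (timings go to the
log, never the manifest). Sample-level QC uses PCA on the imputed log2
matrix with centering but no unit-variance scaling (preserving
intensity-magnitude structure); 95% ellipses are plotting metadata from a
2-D Gaussian fit of group coordinates, with no inferential claim.
`compare_runs` reports per-run F1, identification counts, CV medians and
topN recovery, pairwise deltas, and Wilcoxon comparisons of per-protein CV
distributions on the protein intersection.

## Problem sizes

The bundled simulations use 60 TP + 60 TN + 600 background proteins
(≈ 3,000 precursors × 8 samples) for the default experiment, 1,000
proteins for the null calibration, and 10 seeds × 4 binding levels at
40 + 40 + 200 proteins for the background sweep — sizes at which the
Monte-Carlo error of every asserted quantity is well below its acceptance
margin while the whole suite stays fast.

## Limitations

* Search-engine internals (LFQ summarization, its imputation, the exact
  test behind exported Q-values) are not public; the substitutes here are
  declared, transparent choices and equivalence with any vendor pipeline
  is not claimed.
* The enrichment-score combination rule (sum of min–max-scaled components,
  equal weights) is one realization of "combine −log Q with the log2
  ratio"; the weights are configurable precisely because the choice is
  open.
* Multi-accession protein groups are matched to annotation lists by their
  leading accession only.
* The whole-proteome "significantly upregulated" threshold reuses the
  substrate thresholds for symmetry; there is no published value to pin it
  to.
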