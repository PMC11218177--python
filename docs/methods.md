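# Methods

`multifoci` answers one question about a patient with two spatially separate
tumor foci: did the foci arise independently (multicentric, MC) or does one
descend from the other (metastatic, ME)? The decision is driven by how much
somatic variation the foci share, measured carefully at the read level, and
is surrounded by the companion analyses that typically accompany it in a
multi-region sequencing study: germline susceptibility screening, clonal
deconvolution, copy-number/LOH recurrence and neoantigen prioritization.
Because matched multifocal cohorts are rarely public, the package includes a
synthetic cohort generator whose defaults encode the cohort structure the
analyses were designed for; every stage runs end to end with no external
data.

## Somatic variant sharing

For each somatic call of focus A (restricted to nonsynonymous SNVs and
indels in exonic/splicing regions), the partner focus B's pileup at the same
site is consulted:

1. **coverage gate** — the site must have ≥ 10 total reads in both the
   calling tumor and the matched normal (inclusive), and the call must have
   high-quality alt support (alt depth ≥ 3 and a PASS call; both
   configurable);
2. **shared** — ≥ 1 read carrying the alternative allele in B. A single
   read suffices: this "read-level rescue" deliberately trades specificity
   for sensitivity, because missing a truly shared trunk variant biases a
   patient toward the MC label;
3. **excluded** — no alt reads in B but the site lies in a B LOH segment:
   absence there is uninformative (the allele may have been deleted), so
   the site is removed from both numerator and denominator;
4. **unique** — no alt reads in B, site covered and not in LOH.

Classification runs in both directions and is de-duplicated by
(chrom, pos, ref, alt). The **shared fraction** is Jaccard:
`shared / (shared + unique_A + unique_B)`; excluded-LOH and coverage-failed
sites appear in neither term. The CNV channel shares a gene when both foci
have a same-direction (gain/gain or loss/loss) non-neutral segment over it;
the SV channel matches breakpoint pairs of the same type within a 10 bp
tolerance (both ends; translocations also match end-swapped). Both channels
report Jaccard fractions as well.

## Origin classification and group tests

A patient is MC iff its shared SNV fraction is strictly below a threshold,
default **0.10**. The threshold sits in the middle of the wide empirical gap
between the two bands the generator (and the motivating cohort) realizes —
MC ≤ 2.7 %, ME ≥ 58 % — so any value in roughly [0.05, 0.5] gives identical
labels; ties go to ME as the conservative choice (declaring independent
origin is the stronger claim).

Group comparisons (MC vs ME fractions per channel; germline category counts)
use a Wilcoxon rank-sum test made exact by full enumeration: mid-ranks are
assigned to the pooled sample and all C(n1+n2, n1) rank assignments are
walked, so ties are handled exactly; the two-sided p-value is
min(1, 2·min(P(W ≤ w), P(W ≥ w))). This is feasible up to n1+n2 ≈ 20 and
agrees with `scipy.stats.mannwhitneyu(method="exact")` whenever scipy's
exact path applies (no ties). With complete 6-vs-4 separation the exact
p-value is 2/210 ≈ 0.00952; a normal approximation would report ≈ 0.02 —
the package reports the exact value.

## Germline rare-variant cascade

Retention is a conjunction of four rules — depth ≥ 10×; population AF
(max of dbSNP/1KG/ExAC, missing = 0) ≤ 0.001 **or** COSMIC membership
(cancer-associated sites are kept regardless of frequency); exonic/splicing
and non-synonymous; not in a repeat region — so the retained set is
order-independent and the cascade idempotent; only drop *attribution*
follows the stated order. "Noncoding" is interpreted as everything outside
exonic/splicing (UTR and ncRNA drop with introns/intergenic). Variants with
no recorded depth are dropped under a distinct `no_depth` count rather than
silently passed. Retained variants are intersected with a Cancer Gene
Census-style symbol list (a packaged toy subset; real analyses supply their
own) and tallied by functional category via a packaged gene→category table
(immune, cell_cycle, proliferation, dna_repair, adhesion, other — the table
is a configuration input, not a claim about gene function). Gene-set
enrichment is the hypergeometric upper tail with Benjamini–Hochberg
adjustment across sets.

## Clonal structure

Per-mutation cancer cell fraction:

    CCF = VAF · (purity·CN + (1 − purity)·2) / (purity · multiplicity)

capped at 1.5 (values above 1 signal purity/CN misspecification, not
biology). CN is the overlapping segment's copy number (2 outside segments);
multiplicity is 1 except in gains, where it is round(VAF·CN/purity) clipped
to [1, CN].

Clustering is a **finite binomial mixture** over alt read counts — a
deterministic, desk-scale stand-in for Dirichlet-process CCF clustering
tools, chosen because it produces the same qualitative output (cluster
count, CCF means, assignments) with exact reproducibility and no MCMC.
Component k has CCF c_k; mutation i succeeds with probability φ_i·c_k where
φ_i is its CCF→VAF factor. EM is run for K = 1..K_max (default 6) with 50
k-means++-seeded restarts (default), tolerance 1e-8 on the log-likelihood,
≤ 500 iterations; K is selected by BIC with 2K−1 free parameters; ties and
< 5 mutations fall back to the smaller/single K. A focus with selected
K = 1 is called monoclonal. In practice the dominant clone (CCF ≈ 1) and a
0.4-separated subclone are recovered reliably at 100 mutations and 50×;
small (< 10 mutation) subclones may be merged — BIC is conservative by
design, which is the right failure mode for a monoclonal-vs-multiclonal
call.

**Key mutations** are deleterious mutations in clonal clusters: cluster mean
CCF ≥ 0.5 (the cluster mean, not the noisy per-mutation CCF) and
SIFT ≤ 0.05 **or** PolyPhen-2 ≥ 0.957, boundaries inclusive; a missing score
fails its criterion. Driver recurrence reports, per gene, the number of foci
carrying any mutation in the gene and the subset where one is key.

## CNV / LOH and neoantigens

Segments are 0-based half-open with integer CN, BAF, a genotype string and a
status; gain/loss is relative to ploidy (default 2); LOH iff the genotype
has exactly one distinct allele symbol and CN ≥ 1 (copy-neutral AA included,
CN 0 excluded — with no copies there is no genotype to lose). Gene overlap
is ≥ 1 bp, with no reciprocal-overlap requirement. Overlapping segments
within a focus are rejected. Recurrence is a raw count of non-neutral foci
per gene, thresholded at ≥ 3 foci ("more than 2"), configurable;
significance-of-recurrence modeling is out of scope.

Neoantigen candidacy is per affinity record: mutant affinity strictly
< 500 nM and strictly below the wild-type peptide's. Recurrence counts
distinct foci per mutation (a focus counts once regardless of how many
peptides/alleles pass), thresholded at ≥ 3 foci.

## The synthetic cohort: what it emulates

The default cohort is 10 patients — 6 MC with target shared SNV fractions
{0, 0.5, 1.0, 1.5, 2.0, 2.7} % and 4 ME with {58, 61, 64.5, 67.6} % — on a
5×50 Mb toy genome carrying 60 genes. Choices and their rationale:

* **Trunk sizing.** A target Jaccard fraction f with n variants per focus
  gives trunk size s = 2nf/(1+f), floored for MC (the band is an upper
  bound; integerization must not overshoot it) and rounded for ME.
* **Burden.** 200 somatic SNVs+indels per focus — a placeholder (the
  motivating study does not state per-focus burden) consistent with a
  mid-burden carcinoma exome and large enough for ±0.03 calibration.
* **Reads.** Depth ~ Poisson(50×) tumor / Poisson(30×) normal; alt counts
  Binomial(depth, VAF) with VAF = CCF·purity/(purity·CN + (1−purity)·2).
  Called variants are floored at 3 alt reads (callers only emit supported
  calls); truth-shared variants therefore always have ≥ 1 alt read in both
  foci, and truth-unique variants have exactly 0 in the partner.
* **Clones.** 1–3 clusters per focus with fixed means (1.0 / 0.4 / 0.25
  layouts); trunk and planted drivers are clonal. Patient P04 is
  monoclonal in both foci and P01 in one focus, mirroring the
  monoclonal cases the clustering must flag.
* **LOH.** 1–3 copy-neutral regions of 1–20 Mb per focus; exactly 3
  partner-private variants per focus are deliberately placed inside the
  partner's LOH to exercise the exclusion rule. Ordinary variants are
  placed in genes free of CNV/LOH of either focus, so the exclusion rule is
  exercised only by design, not by accident — without this the random LOH
  overlap would silently shrink the sharing denominator and push MC
  fractions above their band. Consequence: the classifier's realized
  fraction sits slightly above truth (the 6 trapped variants leave the
  denominator), which is why ME minima land near 59.5 % against a 58 %
  target.
* **CNVs/SVs.** CCND1+CTTN gains in every focus and CDKN2A/CDKN2B losses in
  six foci (cohort-wide recurrent events) plus per-patient private CNVs —
  discordant between MC foci, identical between ME foci. 40 SVs per focus;
  MC patients share none (desk-scale counts cannot realize a 0.04 % shared
  fraction except as 0), ME patients share 60 %.
* **Germline.** Totals matched between groups (44–47 per patient); immune
  counts 8–13 (MC) vs 1–4 (ME). Because totals are matched, the immune
  excess in MC is necessarily compensated in the remaining categories, so
  those show a small opposite-direction difference — an arithmetic
  consequence, not a planted signal. Two COSMIC-rescued common variants and
  two decoys per filter rule are added per patient to exercise the cascade.
* **Affinities.** Mutant affinities log-uniform on [10, 5000] nM with
  wild-types drawn independently; planted drivers are forced into candidacy
  (mutant < 450 nM, wild-type 2–20× weaker). A fixed TP53 hotspot site
  recurs in one focus of each MC patient, giving a guaranteed
  cross-patient recurrent neoantigen.
* **Seeds.** Per-patient seeds derive from `SeedSequence([base_seed, i])`;
  identical config+seed reproduces byte-identical output files.

What the generator does **not** emulate: sequencing error and mapping
artifacts (evidence is noiseless given the allele model), realistic genome
geometry and mutational signatures, subclonal CNVs, purity estimation error,
and germline phasing. A green suite therefore establishes that the
*analysis logic* is correct on data satisfying its stated assumptions — not
that the pipeline is robust to caller noise or contamination.

## Numerical and degenerate-input choices

* Coverage and AF boundaries are inclusive ("minimum of 10" ⇒ ≥ 10;
  "greater than 0.001 filtered" ⇒ 0.001 retained); neoantigen thresholds
  are strict (< 500, < wild type); key-mutation boundaries inclusive.
* Empty sharing denominator ⇒ fraction 0 with an explicit warning flag, not
  an error; empty origin group ⇒ missing p-value with a warning.
* EM probabilities are clipped to [1e-9, 1−1e-9] and component CCFs to
  [1e-4, 1.5]; BIC ties break toward smaller K; cluster output is sorted by
  descending CCF.
* Rank-sum tail comparisons use an 1e-9 epsilon so mid-rank sums compare
  exactly under floating-point arithmetic.
* Indels are keyed and classified exactly like SNVs, including the LOH
  rule.

## Known limitations

* The exact rank-sum test is O(C(n1+n2, n1)); beyond ~20 observations an
  asymptotic test should replace it (out of scope here).
* The binomial mixture ignores CCF uncertainty induced by CN estimation and
  assumes a single multiplicity per mutation.
* SV matching is greedy first-match; for the sparse desk-scale breakpoint
  sets generated here this coincides with optimal matching.
* The packaged gene, category and census tables are toys for testing; real
  analyses must supply their own.
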