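# Methods

## Variant identity and normalization

All set algebra operates on normalized `(chrom, pos, ref, alt)` keys.
Normalization trims a shared trailing suffix, then a shared leading prefix,
always leaving at least one base per allele — which preserves the single
VCF-style anchor base of length-changing variants — and adjusts the
position for trimmed leading bases. The procedure is idempotent and keeps
SNP/InDel status invariant (trims remove equal numbers of bases from both
alleles).

Full left-alignment of indels against a reference genome is **not**
performed: the pipeline assumes no reference FASTA, so two placements of
the same indel inside a repeat run remain distinct keys. Inputs produced by
one caller/annotator chain are internally consistent, which is the intended
use; mixing callsets normalized by different conventions is a documented
limitation. Chromosome labels are restricted to GRCh37 names 1–22, X, Y,
MT (a `chr` prefix is stripped; anything else is an error, never silently
kept). Equal-length multi-base substitutions are typed `OTHER` and carried
through the set algebra but excluded from SNP/InDel tallies, matching the
binary partition used in reports.

## Membership classification

Sharing is presence-based on site+allele keys and genotype-blind: the
comparison is between variant lists. Cohort intersection over all patients
is intentionally strict — one patient lacking a call removes the variant.
Control subtraction is applied to both the blood and lesion intersections
*before* classification, so the Venn classes are computed on
control-depleted sets. The five classes partition the union of the two
intersections by the 3-bit (blood, lesion, saliva) presence pattern;
"lesion-specific" requires absence from both the blood intersection and the
saliva set, making the four reported classes disjoint. Blood-only and
blood∩lesion-without-saliva variants are kept under an explicit `Excluded`
class so reports can account for every variant; published summary tables
omit them, and the tally functions do likewise.

VCF ingestion keeps records whose FILTER is PASS or missing (`.`), the GATK
convention; anything else is dropped. Multi-allelic records contribute one
key per ALT; symbolic and spanning alleles carry no comparable sequence and
are skipped.

## Region and effect vocabulary

Region and exonic-effect strings are mapped onto fixed vocabularies in the
upstream annotator's dialect (`exonic`, `UTR5`, `ncRNA_exonic;splicing`,
…). Unrecognized strings raise rather than degrade to `NA`. "Nonsense" and
"stopgain" are one level. The derived `Intragenic` row sums the seven genic
region rows; `Total variants` sums all disjoint top-level rows; `(Total
Genes)` counts distinct `;`-split symbols. The exonic-effect table is
restricted to regions `exonic`, `exonic;splicing` and `splicing`. The
nonsynonymous subset keeps missense + stop-gain + `unknown` effects —
`unknown` counts as nonsynonymous in this pipeline's convention — and
excludes synonymous changes.

One transcription note: in the packaged effect-count fixture, the printed
total of the SNP common-group column (1866) is one less than the sum of its
printed cells (882 + 925 + 52 + 8 = 1867). The fixture ships the printed
values verbatim; the tally code, run on records, always reports true column
sums, so this single printed inconsistency is documented rather than
reproduced by the arithmetic. The region fixture's exonic-region InDel
totals also differ slightly from the effect fixture's column totals for two
columns; each fixture is internally checked against its own derived rows.

## Rarity and consensus classification

A record is rare when each of its three population frequencies (1000
Genomes phase 3, NHLBI ESP, ExAC) is missing or strictly below the
threshold (default 0.01); missing counts as rare. Frequencies are used as
reported alternate-allele frequencies, not folded to minor alleles —
folding is a no-op below 0.01, so the distinction cannot change the
filter's output at the default threshold.

Predictor letters are never trusted from input; they are recomputed from
numeric scores (SIFT deleterious strictly below 0.05; PolyPhen-2 HDIV
damaging ≥ 0.957 / possibly ≥ 0.453, HVAR ≥ 0.909 / ≥ 0.447). The
consensus rule takes two flags — SIFT deleterious, and *both* PolyPhen-2
models at least possibly damaging — giving concordant-deleterious (both),
discordant (exactly one), not-damaging (neither, all scores present), or
unscored (any score missing). Requiring both PolyPhen models is what keeps
a SIFT-tolerated variant with a split PolyPhen verdict (HVAR benign, HDIV
possibly damaging) out of the discordant bin. The rule is monotone: lowering
a SIFT score never moves a record away from deleteriousness.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
including the observed count (P(X ≥ k)), computed by scipy's survival
function (log-space, stable for universes ≥ 1e5). Benjamini–Hochberg
adjustment (statsmodels) runs within each namespace separately, because GO
classes and KEGG are conventionally tested as separate families; with no
namespace map all terms form one family. The universe is configurable; the
CLI defaults to the union of all GMT genes when none is supplied. Ties are
broken lexicographically by term for deterministic reports. Term databases
themselves (GO/KEGG releases, clustering of terms into networks) are out of
scope: the statistic is the deliverable, the gene sets are user input.

## Synthetic cohorts

The generator emulates the paired-design study shape: ten patients by
default, each with a blood and a lesion callset; planted blocks of variants
shared by all patients in the configured Venn class; ten control-overlap
variants that the subtraction step must remove; fifteen patient-private
noise variants per patient that the strict intersection must discard
(guaranteed for ≥ 2 patients); and an indel fraction of 0.25, the
approximate shared-variant SNP:InDel ratio in exome cohorts of this design.
Planted counts are tens per class — large enough to exercise every code
path, small enough that the 25-cohort recovery check runs in seconds.

Coordinates are drawn without replacement on chromosomes 21 and 22 (a
2 Mb space per chromosome), which exercises normalization and
cross-chromosome sorting without a reference genome. Indel alleles are
constructed minimal (the variable tail never ends in the anchor base).
Predictor scores for planted consensus classes are drawn from the interior
of each class-defining region — e.g. concordant: SIFT in [0, 0.045),
both PolyPhen-2 in [0.96, 1]; not-damaging: SIFT ≥ 0.1, PolyPhen ≤ 0.4 —
so no planted classification sits on a bin boundary. Non-rare planted
variants always receive at least one population frequency ≥ 0.02. A single
`numpy.random.default_rng(seed)` instance drives all draws; no global state
is touched, and identical configs produce byte-identical files.

What the generator does **not** emulate: realistic allele-frequency
spectra, linkage, per-patient genotype noise or caller error, tumor purity,
and read-level artefacts. Passing the planted-truth recovery check
demonstrates that the set algebra, classification and filtering are exact
on clean inputs, not that the pipeline is robust to caller disagreement —
robustness to that lives upstream, in the caller and its filters.

## Problem sizes and determinism

The recovery surface uses 25 cohorts of 4 patients with the default planted
composition (120 manifest variants each), which keeps the whole suite and
the acceptance script to a few seconds while covering every membership
class, both variant types, and all four consensus classes in every cohort.
Property tests (hypothesis) run derandomized with fixed seeds. The
acceptance script derives each cohort seed from the user-supplied `--seed`
and reports the recovery rate over all manifest entries.

## Known limitations

* Trim-only normalization (no reference-based left alignment), as above.
* Presence-based sharing ignores genotypes: a site called heterozygous in
  one patient and homozygous in another is "shared".
* The lesion-specific class is a cohort-level definition (in the lesion
  intersection, absent from blood intersection and external set), not a
  per-patient tumor/normal subtraction; per-patient somatic calling with
  allele-fraction models is a non-goal.
* SIFT/PolyPhen-2 scores apply to missense SNVs; InDels and unknown-effect
  variants surface as `unscored` and need orthogonal evidence.
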