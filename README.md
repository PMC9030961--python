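# varsieve

Cohort-wide exome variant filtration and prioritization for paired
blood/lesion callsets, with an external disease-cohort comparison, a
population-control subtraction, rare-variant consensus pathogenicity
classification, and gene-set enrichment.

## The problem

Small case-series exome studies of medication-related osteonecrosis of the
jaw (MRONJ) — and of similar conditions where a diseased tissue and blood
are sequenced from every patient — need to turn per-patient GATK/ANNOVAR
callsets into a short, defensible list of candidate variants. The standard
strategy, implemented here as a reusable library and CLI, is:

1. **Strict cohort intersection.** For each tissue, keep only variants
   present in *every* patient's callset: blood-shared variants are germline
   candidates, lesion-shared variants are somatic candidates.
2. **Control subtraction.** Remove variants found in a population control
   archive (e.g. KOVA for Korean cohorts) to discard ancestry-common
   variation: `B = blood_shared \ control`, `L = lesion_shared \ control`.
3. **Venn membership.** Each surviving variant is classified by its
   presence pattern across `B`, `L`, and an external disease-cohort variant
   set `S` (e.g. saliva exomes of independent patients):
   `S∩B∩L`, `S∩B`, `S∩L`, lesion-specific (`L` only — the somatic
   candidates), or excluded (blood-supported without external support).
4. **Region/effect tallies.** Count matrices of region (exonic, intronic,
   UTR, …) and exonic effect (missense, synonymous, stop-gain, frameshift
   and non-frameshift indels, unknown) per membership class and variant
   type (SNP vs InDel), with derived Intragenic / Total / distinct-gene
   rows. "Nonsynonymous" means missense + stop-gain + unknown.
5. **Rare-variant prioritization.** Keep variants with alternate-allele
   frequency < 0.01 (or absent) in *all three* of 1000 Genomes, NHLBI ESP
   and ExAC, then classify each scored SNV by SIFT and PolyPhen-2
   consensus: SIFT deleterious means score < 0.05; PolyPhen-2 support
   means **both** the HDIV and HVAR models call at least "possibly
   damaging" (HDIV ≥ 0.453, HVAR ≥ 0.447; "probably damaging" at ≥ 0.957
   and ≥ 0.909). Both supports → concordant-deleterious; exactly one →
   discordant; neither → not damaging; missing scores → unscored.
6. **Gene-set enrichment.** Over-representation of candidate genes in
   user-supplied GMT gene sets via the upper-tail hypergeometric
   probability
   `p = Σ_{i≥k} C(K,i) C(N−K, n−i) / C(N,n)`
   with Benjamini–Hochberg FDR adjustment per namespace (BP/CC/MF/KEGG).

Because studies of this design rarely deposit raw data, the package ships
two validation surfaces: a seeded synthetic-cohort generator with a full
truth manifest (every planted variant's membership class, type, rarity and
consensus class must be recovered exactly by the pipeline), and verbatim
transcriptions of a published study's summary tables, against which the
classifier reproduces every printed SIFT/PolyPhen letter and count.

## Worked example

Classify the packaged 31-row rare-variant table (24 SNPs in *KRT18*,
*MUC5AC*, *NBPF9*, *PABPC3*; 7 InDels):

```python
from collections import Counter
from varsieve import table_fixtures, prioritize_candidates

fixtures = table_fixtures()
candidates = prioritize_candidates(fixtures["rare_annotations"])
print(Counter(candidates["variant_type"]))
print(Counter(candidates["consensus_class"]))
print(candidates.loc[candidates["consensus_class"] == "concordant_deleterious",
                     ["key", "gene", "hgvs_p", "sift_score", "sift_call",
                      "pp2_hvar_call", "pp2_hdiv_call"]].to_string(index=False))
```

prints

```
Counter({'SNP': 24, 'INDEL': 7})
Counter({'not_damaging': 12, 'unscored': 10, 'discordant': 6, 'concordant_deleterious': 3})
            key   gene  hgvs_p  sift_score sift_call pp2_hvar_call pp2_hdiv_call
12:53343069:G:T  KRT18  p.G38C       0.009         D             D             D
12:53343084:G:C  KRT18  p.G43R       0.001         D             P             P
13:25671027:A:G PABPC3 p.K231E       0.001         D             D             D
```

All 31 variants pass the three-database rarity filter; three SNVs are
deleterious by SIFT *and* at least possibly damaging by both PolyPhen-2
models (the concordant candidates), six are flagged by exactly one
predictor, and every scoreless row — the InDels and the unknown-effect
SNVs — is reported as unscored rather than silently dropped.

The same pipeline runs from the shell on a synthetic cohort:

```sh
varsieve simulate --out sim --seed 7
varsieve classify --cohort sim/cohort_map.tsv --control sim/control.tsv \
                  --saliva sim/saliva.tsv --annotations sim/annotations.tsv --out out
varsieve prioritize --annotations sim/annotations.tsv \
                    --membership out/membership.tsv --out out
varsieve report --in out
```

The classify stage logs a conservation check at every filter:

```
INFO varsieve: cohort intersection: blood 908 -> 82 shared, lesion 1142 -> 108 shared
INFO varsieve: control subtraction: blood 82 = 72 kept + 10 removed; lesion 108 = 98 kept + 10 removed
INFO varsieve: SNP membership: Saliva;Blood=9, Saliva;Lesion=7, Saliva;Blood;Lesion=42, Lesion-Specific=19, Excluded=0
```

— 908 raw blood calls across ten patients intersect to 82 shared variants,
the 10 planted control-overlap variants are subtracted, and the remaining
variants partition into the Venn classes recorded in `sim/manifest.tsv`.

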