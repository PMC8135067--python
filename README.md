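# ovatome

Tools for a comparative ovary study design: two conditions (a neuropeptide
knockout and a wildtype animal), one bulk RNA-seq library each, plus
histology and qPCR follow-up. The package implements the complete
computational chain of such a study as a tested, reusable pipeline:

1. **Read cleaning** — PCR duplicates are defined operationally: two reads
   are duplicates when their first 10 bases are identical **and** the whole
   reads are more than 90% similar. Clusters are the single-linkage closure
   of this relation; one representative per cluster is kept. Adapter
   trimming and mean-quality filtering are provided with documented,
   configurable defaults.
2. **Expression quantification** — FPKM from fragment counts and transcript
   lengths: `FPKM = c · 10⁹ / (L · N)` for `c` fragments on a transcript of
   `L` nt in a library of `N` mapped fragments. A gene is *expressed* when
   FPKM > 5 (strict), *up in mutant* when FPKM_mut / FPKM_wt > 2, and *up in
   wildtype* when that ratio is < 0.5. No statistical test is involved —
   the design has one library per condition.
3. **Comparative GO enrichment** — on the `is_a` ontology graph, with
   ancestor-closed annotations, each term *t* gets a signed score

   `score(t) = log₂((f_A(t) + ε) / (f_B(t) + ε))`

   where `f_X(t)` is the fraction of condition-specific gene set *X*
   annotated to *t* and `ε` is a fixed pseudo-count (default 0.01). Positive
   scores = enriched among mutant-specific genes (red), negative = wildtype
   (blue). For the Cytoscape graph view, terms at GO level < 2 (shortest
   `is_a` distance from the namespace root) or with |score| < 1.2 are drawn
   as zero-sized nodes.
4. **Follicle morphometry** — follicles are staged by diameter (I ≈ 50 µm,
   II ≈ 70 µm, III ≈ 100 µm; boundaries at the 60/85 µm midpoints), and
   each section is summarized as counts, follicles/mm², and the stage-III
   percentage, with fold comparisons between sections.
5. **qPCR** — ΔΔCt relative expression against a reference gene
   (Ci-GAPDH) with the wildtype as calibrator: `RQ = 2^(−ΔΔCt)`.

A synthetic-data module generates every input with known ground truth
(planted duplicate clusters, planted fold changes, planted GO enrichment,
stage-structured follicle diameters, known ΔΔCt), so the whole pipeline runs
and is validated without any sequence download.

## Worked example

```
$ ovatome demo --seed 42 --out demo/
demo complete; manifest at demo/manifest.json
  simulate: ok
  dedup: ok
  quant: ok
  enrich: ok
  morpho: ok
  qpcr: ok
```

The demo simulates all inputs, then runs every stage. Inspecting the
outputs:

```
$ ovatome dedup --in demo/reads.fastq --out demo/clean.fastq
kept 219/273 reads (54 duplicates removed)

$ ovatome quant --counts demo/counts.tsv --out demo/quant.tsv
call
unchanged         412
up_in_mutant       46
up_in_wildtype     42

$ ovatome morpho --follicles demo/follicles.csv --area-mm2 5.52
{"area_mm2": 5.52, "n_total": 355, "n_stage3": 35,
 "density_total": 64.3, "density_stage3": 6.34, "prop_stage3": 9.9}

$ ovatome qpcr --ct demo/ct.csv
             gene      ddct       rq     fold direction                     label
             MLH3 -1.284893 2.436639 2.436639    higher 2.4-fold higher in mutant
ceramide-synthase  0.537559 0.688935 1.451515     lower  1.5-fold lower in mutant
```

Read the numbers as follows: 54 of 273 simulated reads fell in planted
duplicate clusters and were removed; 46 genes pass the ratio > 2 call in the
mutant direction against 40 planted (the excess is threshold noise on a
single-library comparison); the simulated wildtype-like section carries 6.34
stage-III follicles/mm² (9.9% of all follicles); and the Ct table planted at
a 1.5-fold deficit of ceramide synthase in the mutant recovers as "1.5-fold
lower" within replicate noise.

Every threshold is exposed: `ovatome enrich --pseudo 0.01 --band 1.2
--min-level 2`, `ovatome quant --fpkm-min 5 --ratio 2`, and so on. A YAML
config drives `ovatome run --config run.yaml`; each run writes a manifest
with the config snapshot, seed and per-file SHA-256 digests, which are
bit-identical across reruns with the same seed.

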