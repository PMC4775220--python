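# ripcall

Binding-site discovery for RIP-seq (RNA immunoprecipitation sequencing)
experiments, for analysts comparing an antibody pulldown against an IgG
control, plus the splicing-ratio quantitations that typically accompany
such a study. The package provides the complete computational path from
aligned fragment intervals to annotated binding sites, and a synthetic-data
generator with planted ground truth so every stage can be validated without
external data.

## The method

**Peak detection.** Per-base fragment coverage is convolved with the second
derivative of a Gaussian (a Laplacian-of-Gaussian, "Mexican hat" filter) of
bandwidth σ = 300 nt. A coverage bump of width ≈ σ produces a strongly
negative response; candidate peaks are maximal negative-response runs
bounded by the flanking zero crossings, scored by −response at the summit.
Because the truncated kernel is mean-centred (Σw = 0 exactly), calls are
invariant to constant background shifts and scale linearly with coverage.

**Differential enrichment.** Fragments are counted per peak per sample by
midpoint assignment. Library sizes are corrected by DESeq-style
median-of-ratios size factors s_j = median_i ( k_ij / (Π_v k_iv)^{1/m} ).
For each peak, a two-sided conditional exact test under a negative-binomial
model (per-peak dispersion α̂ = max(method-of-moments estimate, fitted
trend a₀ + a₁/μ)) asks whether the split of the total count between RIP and
control is surprising. Peaks with Benjamini–Hochberg FDR < 0.05 **and**
more normalized reads in the RIP condition are reported as binding sites.

**Annotation.** Each significant peak is assigned, by its summit, to a gene
and a region class — 5'UTR, CDS, intron, or 3'UTR — of the covering
transcript (precedence 3'UTR > 5'UTR > CDS > intron across isoforms),
and the class distribution and bound-gene list are summarised.

**Splicing.** Percent spliced in (Ψ) is estimated from junction reads with
a Beta-binomial model after junction-count normalization (a skipped exon
has two inclusion junctions but one exclusion junction); the evidence that
two conditions differ in Ψ is a closed-form Bayes factor
BF = B(i₁+1, e₁+1)·B(i₂+1, e₂+1) / B(i₁+i₂+1, e₁+e₂+1).
qPCR isoform ratios use the ΔΔCt method: relative expression = 2^(−ΔΔCt).

## Worked example

```python
from ripcall.pipeline import PipelineConfig, SimulateConfig, run_pipeline
from ripcall import match_peaks_to_sites

cfg = PipelineConfig(seed=42)
cfg.simulate = SimulateConfig()   # 40 genes, 20 planted sites, 8x enrichment,
                                  # 2 RIP + 2 IgG, ~200 nt fragments
res = run_pipeline(cfg, "example_run")
m = match_peaks_to_sites(res.peaks, res.sites)
print(len(res.peaks), len(res.significant), m.recall, m.precision)
print(res.significant[["peak_id", "log2_fold_change", "fdr"]].head(3))
```

prints

```
20 20 1.0 1.0
  peak_id  log2_fold_change           fdr
0  peak_1          2.936712  3.807417e-10
1  peak_2          2.975195  1.684015e-13
2  peak_3          2.695792  4.895979e-20
```

— all 20 planted sites are recovered as candidate peaks (recall 1.0) with
no false candidates (precision 1.0), every one significant at FDR < 0.05
with ~8-fold (log2 ≈ 2.9 after background dilution) RIP enrichment. The
output directory contains the peak BED/TSV, the enrichment table, annotated
significant sites, coverage bedGraph, the planted truth, and a manifest
with parameter values and input checksums.

The same analysis runs from the shell:

```bash
ripcall simulate --genes 40 --sites 20 --outdir sim/
ripcall run --config config.yaml --outdir out/
```

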