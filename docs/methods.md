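# Methods

This note documents the models and numerical choices behind ripcall: what
the pipeline computes, what the synthetic data emulate, and where the
design was genuinely open.

## Coordinates and conventions

All genomic intervals are 0-based, half-open (`[start, end)`), matching
BED; GTF's 1-based inclusive coordinates are converted only at the GTF
boundary. Coverage is unstranded; strand is kept on transcripts solely for
region classification (on the minus strand the 5'UTR lies at higher
genomic coordinates).

## Synthetic data generator

The generator defines the study conditions the pipeline is validated
under; it is a first-class, tested module, not a fixture.

- **Design**: two RIP replicates and two IgG control replicates, mirroring
  a paired-replicate immunoprecipitation experiment with an IgG background
  control.
- **Gene models**: disjoint three-exon genes (two introns, CDS spanning the
  middle exon and parts of the flanking exons, non-empty UTRs on both
  sides). Length ranges are fixed so that every region class offers a
  contiguous run of ≥ 600 nt, i.e. one default-width binding site fits in
  any class, and a single gene always fits on a 10 kb chromosome.
- **Planted sites**: width 600 nt (≈ 2σ of the detection bandwidth),
  enrichment 8-fold, drawn from a region-class mix defaulting to
  {intron 0.55, 3'UTR 0.41, 5'UTR 0.02, CDS 0.02} — the intron-heavy
  binding profile typical of nuclear RNA-binding proteins. Sites are
  pairwise separated by ≥ 4× width so two sites can never merge into one
  detected peak.
- **Fragments**: the transcribed genome (gene spans by default; a `flat`
  mode covers whole chromosomes) is tiled into 200 nt windows split at site
  edges. Window counts are gamma-Poisson (negative binomial) with mean
  `background_rate × window_length` (default rate 0.05 fragments/nt ≈ 10×
  base coverage at 200 nt fragments) times the enrichment factor inside
  planted sites in RIP samples, and dispersion α = 0.05 — a realistic
  replicate-to-replicate overdispersion for cell-line material. Fragment
  midpoints are uniform within their window; lengths are shifted-Poisson
  with mean 200 nt and floor 50 nt (any unimodal choice around the stated
  mean is acceptable; this one is recorded in the config). Per-sample
  randomness comes from spawned seed substreams, so outputs are
  deterministic per seed and independent of how many samples are drawn.

What the generator does **not** emulate: sequence content (no FASTA/FASTQ,
no alignment artefacts), PCR duplicates, GC or mappability bias, stranded
libraries, isoform-level expression variation, or dispersion trends across
loci. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated generative model — not that real
libraries are free of those artefacts.

## Peak detection

The LoG kernel is g''(x) = g(x)(x² − σ²)/σ⁴ evaluated at integer offsets,
truncated at radius 4σ and then mean-centred so Σw = 0 *exactly*; exact
centring is what makes peak calls invariant to constant background shifts
even after truncation. Convolution uses overlap-add FFT (`scipy.signal`),
verified against a direct double-loop oracle to 1e−9. The first and last
`radius` positions of the response are set to zero: there the zero-padded
convolution reflects the finite track, not the signal, and a constant
track would otherwise produce spurious edge runs.

Negative-response runs are merged when separated by < 50 nt, filtered at
minimum width 50 nt and mean coverage ≥ 5, and scored by −response at the
summit (argmin, leftmost on ties). A tiny threshold (1e−12) defines
"negative", so float round-off from the FFT cannot flip run boundaries.

**Score threshold.** The default is adaptive: k × MAD of the response over
positions with non-zero response (positions beyond the kernel radius of
any coverage carry no information about the background response scale).
k = 6 rather than the 3–4 conventional for per-position robust
thresholding: a peak's score is the *maximum* of −response over a run, so
under the null it follows the extreme-value distribution of thousands of
effectively independent kernel-width windows, whose upper tail sits at
4–5× MAD. Empirically (default conditions) noise-run maxima reach 4.7×
MAD while true-site scores exceed 24× MAD, so k = 6 separates the two
populations with a wide margin on both sides. The threshold, k, and all
other detection parameters are config-exposed.

Detection runs on pooled raw RIP coverage (replicates summed). Raw rather
than RPM signal is the default because the downstream count test handles
library size explicitly; a config flag selects RPM. Per-replicate
detection is available by disabling pooling.

## Differential enrichment

- **Counting**: fragment-midpoint assignment, so each fragment is counted
  in at most one peak; an any-overlap mode would double-count fragments
  spanning peak boundaries.
- **Size factors**: median-of-ratios to per-row geometric means. At
  pipeline level the factors are estimated from a genome-wide 2 kb bin
  count matrix rather than from the peak matrix: with a handful of
  candidate peaks, nearly all genuinely enriched, the median ratio over
  peak rows absorbs the enrichment itself and cancels the signal, whereas
  genome-wide bins are overwhelmingly background and estimate relative
  sequencing depth. (With genome-scale peak lists, where most rows are
  null, the two choices agree.) The `size_factors` function itself is the
  plain median-of-ratios estimator and works on any matrix.
- **Dispersion**: per-peak method of moments on normalized counts,
  α_i = max(0, (v̂ − μ̂)/μ̂²) with v̂ the pooled within-condition variance,
  stabilised by a trend α(μ) = a₀ + a₁/μ fitted by least squares across
  peaks on the **raw** (possibly negative) moment estimates and clipped at
  zero. Fitting only positive estimates would bias the trend upward by
  ≈ 1/μ under the null (the conditional mean of the positive half of a
  noisy unbiased estimator), destroying test calibration with 2 + 2
  replicates. The final per-peak value is max(α_i, trend(μ_i)) — a
  conservative sharing rule appropriate for two replicates per condition.
- **Exact test**: conditional on the total count K of a peak, each split
  (a, K − a) between conditions is weighted by the product of the two
  condition-sum likelihoods (negative binomial moment-matched to the mean
  and variance implied by the size factors and α̂; Poisson when α̂ = 0);
  the two-sided p-value is the normalized probability of all splits no
  more likely than the observed one (with a 1e−9 relative tie tolerance).
  Verified against a pure-Python enumeration oracle for all totals ≤ 50.
  Zero-count peaks get p = 1, keeping peak and result lists aligned 1:1.
- **Gating**: Benjamini–Hochberg adjustment (statsmodels), significance =
  FDR strictly below 0.05 **and** RIP-direction enrichment.

Calibration measured under the generator's null (α = 0.05, 2 vs 2, depth
factors 0.9–1.2): the raw p < 0.05 fraction averages ≈ 0.036 — mildly
conservative, as expected from the max() dispersion rule — and the BH
false-discovery proportion over repeated simulations stays ≤ 0.05.

## Annotation

Summit-based, single-label classification: one class per binding site.
When isoforms disagree at a summit, precedence is 3'UTR > 5'UTR > CDS >
intron (UTR annotations are usually the isoform-specific, biologically
informative ones), then longer transcript, then lexicographic id — all
config-overridable. Noncoding transcripts classify exonic positions as
`exon_noncoding`, reported separately and excluded from the four-class
fractions, as are intergenic peaks.

## Splicing quantities

Ψ uses a conjugate Beta model on junction-normalized counts
(I' = I/n_inc_junctions, E' = E/n_exc_junctions; SE and RI have two
inclusion junctions and one exclusion junction) with a uniform Beta(1,1)
prior; the posterior is Beta(1 + I', 1 + E') and Ψ̂ its mean, with a 95%
equal-tailed credible interval. The Bayes factor compares independent
uniform-prior Ψ per condition against a shared Ψ; both marginals are Beta
functions, computed via `betaln` for stability, with effective counts
rounded half-up to integers (impact < 1e−3 on BF for counts ≥ 10, verified
against quadrature). Event types other than SE/RI are parsed and carried
through with counts but no Ψ/BF, and are flagged as such. This is a
deliberately simple stand-in for a full generative splicing model: it
makes the same accept/report decision (BF above a threshold,
conventionally 2) but does not model read positions or isoform lengths
beyond junction multiplicity.

ΔΔCt: relative expression 2^(−[(Ct_t − Ct_ref)_s1 − (Ct_t − Ct_ref)_s2]);
isoform ratios are per-replicate ratios of relative expressions,
summarised as mean ± sample sd over ≥ 3 replicate experiments. Raw ratios
are reported; cross-condition normalization (e.g. to a vector control) is
left to the caller.

## Pipeline

One YAML config (unknown keys rejected) with defaults fixed at the method's
stated operating point: bandwidth σ = 300 nt, FDR threshold 0.05, mean
fragment length 200 nt, 2 + 2 replicates. All stage randomness derives from
the single run seed via SHA-256-named substreams, so runs are reproducible
byte-for-byte and each stage can be re-run from its on-disk inputs.
Problem sizes used by the test suite and the acceptance script — a 40-gene
/ 600 kb chromosome with 20 sites for recovery, 150 genes / 1.6 Mb with
200 sites for the region-mix study, 20 × 2000 peaks for null calibration —
are chosen so each statistical check has adequate resolution (e.g. ±3
s.e. of a binomial fraction well inside the stated tolerance) while a full
run stays in the seconds-to-a-minute range.

## Known limitations

- The conditional exact test enumerates all K + 1 splits; cost is linear
  in the peak's total count (fine at these depths, O(10⁴) worst case).
- Dispersion is shared only through the 1/μ trend; no empirical-Bayes
  shrinkage of the kind larger designs would warrant.
- Exactly a two-condition design; no covariates or GLM.
- Single detection bandwidth per run; no scale-space search for sites much
  narrower or wider than σ.
- Dense per-chromosome coverage vectors assume chromosomes of toy-to-small
  genome scale (8 bytes/nt); human-genome scale would want a sparse or
  chunked representation.
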