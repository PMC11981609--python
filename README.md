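# bcdms

Barcode-resolved deep mutational scanning (DMS) analysis. The package
estimates per-variant functional effects from raw barcode expression counts
with a per-position negative-binomial mixed model, and builds the
cross-condition analyses that sit on top of those effects: corrector
defect/rescue contrasts, a PCA-based signaling-bias score, and Bayesian
errors-in-variables meta-regression for ligand-specific variant discovery.
A generative simulator with known ground truth stands in for sequencing
data, so every stage is testable end to end.

## Model

For each protein position, counts of all its variants' barcodes plus the
wild-type barcodes of the same subregion follow

```
count_ijkm ~ NB(mu_ij, theta)           Var = mu + mu^2/theta
log mu_ij  = beta_cond[i] + beta_var[j,i] + alpha_k + offset(gamma_m)
alpha_k    ~ N(0, sigma^2)
```

for condition *i*, variant *j*, barcode *k*, sample *m*. The WT deviation is
fixed at zero (reference coding); `alpha_k` is shared by every sample of a
barcode, which is how barcode information is pooled across replicates and
conditions; `gamma_m` is the natural log of the summed counts of nonsense
(stop) barcodes in sample *m*. Each scalar `alpha_k` is integrated out by a
Laplace approximation with an analytic gradient for the outer maximum
likelihood problem; Wald standard errors come from the inverse observed
information. Effects are reported as log2 fold changes versus wild-type
with Benjamini-Hochberg q-values (per-condition scope by default).

Unobserved (barcode, sample) pairs are explicit zeros, not missing data:
the assay reads out RNA, so absence of a mapped barcode from a sample is
evidence of low expression, and dropping those barcodes would discard the
strongest loss-of-function signal.

## CLI

```
bcdms simulate  --seed 1 --out out/sim            # synthetic dataset + truth
bcdms map       --reads-rep1 r1.fastq --reads-rep2 r2.fastq \
                --design out/sim/design.tsv --out out/map
bcdms count     --map out/map/map.tsv --samples samples.tsv \
                --reads s1=s1.fastq --reads s2=s2.fastq --out out/counts
bcdms fit       --counts out/sim/counts.tsv --samples out/sim/samples.tsv \
                --out out/fit
bcdms contrasts --counts ... --samples ... --control DMSO \
                --treated Ipsen17 --out out/ct
bcdms bias      --effects out/fit/effects.tsv --pc2-cutoff 7.5 --out out/bias
bcdms ligand    --effects out/fit/effects.tsv --x-condition THIQ_low \
                --y-condition aMSH_low --out out/lig
bcdms power     --counts ... --samples ... --position 5 --out out/power
```

Everything is plain TSV/JSON; each stage writes a manifest with input
hashes, seeds and the package version, and reruns with the same inputs are
byte-identical. The variant-barcode map applies the standard filter chain
in both mapping replicates: barcode length exactly 21, read depth strictly
greater than 10, and purity (majority-pair reads over all reads carrying
the barcode) strictly greater than 0.75.

## Layout

- `bcdms.simulate` — generative simulator (counts and reads) with ground truth
- `bcdms.mapping` — variant-barcode map building and purity/depth filtering
- `bcdms.counts` — count-table assembly, stop-derived offsets, QC
- `bcdms.glmm` — the NB mixed model, effect tables, BH, LoF/GoF classes,
  residue sensitivity, barcode down-sampling
- `bcdms.contrasts` — marginal means, defect/rescue contrasts, rescue classes
- `bcdms.multicond` — stat-matrix PCA with bias flags; errors-in-variables
  meta-regression with residual-based specificity labels
- `bcdms.cli` — pipeline subcommands
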