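# sphmm

Semi-parametric hierarchical mixture modelling of GWAS summary statistics:
estimate how many SNPs are associated with a disease and how large their
effects are, then project how many genome-wide-significant discoveries a
future, larger study would make.

## Who this is for

Statistical geneticists planning case/control GWAS. Given only published
per-SNP summary statistics (log odds ratios and their variances) from an
existing study, the package answers two design questions:

* what fraction of (nearly independent) SNPs is associated with the
  disease, and with what effect-size distribution;
* how many cases and controls a future study needs to detect a target
  number of genome-wide-significant SNPs.

## The model

For an LD-pruned set of m SNPs, the observed log-odds-ratio estimate
y_j with known variance V_j follows a two-component mixture

```
f_j(y_j) = (1 − π) · N(y_j; 0, V_j) + π · Σ_k p_k · N(y_j; b_k, V_j)
```

where π is the prior probability that a SNP is non-null and the effect
size distribution g of non-null SNPs is non-parametric: a discrete
distribution with masses p = (p_1 … p_B) on a fixed grid of nonzero
log-OR values b = (−0.300, −0.295, …, −0.005, 0.005, …, 0.300), B = 120.
(π, p) are estimated by an EM algorithm — empirical-Bayes estimation of
the priors from the data themselves.

Prediction then follows from the fitted mixture. With z_c the two-sided
normal quantile of the significance level p_c (5×10⁻⁸ genome-wide
"significant", 1×10⁻⁶ "suggestive"), the probability that SNP j is
significant in a future study with n_r\* cases and n_s\* controls is

```
P_j = (1 − π) · p_c + π · Σ_k p_k · Power_j(b_k),
```

with Power_j evaluated at the rescaled variance
V_j · (1/n_r\* + 1/n_s\*) / (1/n_r + 1/n_s) — the variance of a log-OR
estimate is approximately proportional to the sum of inverse case and
control sizes. The expected number of significant SNPs among m\*
independent SNPs is K = m\* × mean_j(P_j), a function of the effective
number of cases n_e\* = 2 / (1/n_r\* + 1/n_s\*). Uncertainty in π̂ and K̂
comes from a parametric bootstrap (simulate from the fitted model,
refit, repeat).

## Worked example

Simulate a study of 10,000 cases and 10,000 controls over 20,000
independent SNPs in which 20% of SNPs carry effects of ±0.05 (odds ratio
≈ 1.05), fit the mixture, and project discoveries:

```bash
$ sphmm simulate --m 20000 --pi 0.2 --effect 0.05 \
    --n-cases 10000 --n-controls 10000 --seed 7 \
    --out sim.tsv --truth-out truth.tsv
wrote 20000 SNPs to sim.tsv

$ printf 'snp_a\tsnp_b\tr2\n' > ld.tsv   # no LD in this simulation

$ sphmm fit --summary sim.tsv --ld ld.tsv \
    --n-cases 10000 --n-controls 10000 --seed 7 --outdir run
pi_hat = 0.2251 over m = 20000 pruned SNPs -> run/fit.json
```

The estimated proportion of disease-associated SNPs is π̂ = 0.225
(truth: 0.2). Project the number of significant SNPs per 100,000
independent SNPs as the study grows:

```bash
$ sphmm predict --fit run/fit.json --pruned run/pruned.tsv \
    --n-cases 10000 --n-controls 10000 --m-star 100000 \
    --ne-min 5000 --ne-max 160000 --ne-points 7 --out curve.tsv
wrote 7-point discovery curve to curve.tsv

$ sphmm required-n --fit run/fit.json --pruned run/pruned.tsv \
    --n-cases 10000 --n-controls 10000 --m-star 100000 \
    --k-target 1 --k-target 10 --k-target 100
k_target=1      n_e_star=5000
k_target=10     n_e_star=9000
k_target=100    n_e_star=16000
```

Reading: about 16,000 effective cases (16,000 cases plus 16,000
controls, or any unbalanced design with the same harmonic combination)
would be needed for 100 genome-wide-significant SNPs out of 100,000
independent SNPs under this architecture. Uncertainty:

```bash
$ sphmm bootstrap --fit run/fit.json --pruned run/pruned.tsv \
    --n-cases 10000 --n-controls 10000 --n-boot 30 --m-star 20000 \
    --future-cases 20000 --future-controls 20000 --seed 7 --out boot.tsv
pi_se = 0.02093; K CI (95%) = (43.53, 139.33); replicates -> boot.tsv
```

With real consortium summary files, point `sphmm fit` at the downloaded
file with `--columns` naming its header (e.g.
`--columns "snp=SNP,a1=A1,a2=A2,or=OR,se=SE"`), give it a pairwise LD
table and optionally a reference-panel SNP list and an
ancestral/derived allele map; the pipeline harmonises, filters, prunes
at r² > 0.1, and fits. `sphmm validate` fits a "current" study and
compares its prediction against the observed count in a larger "future"
study.

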