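# snvppv

Estimate the proportion of true positives (PPV, a.k.a. precision) of a
human SNV call list from call-set summary statistics, with honest 95%
prediction intervals for the observed PPV.

## Who this is for

Anyone holding a VCF of single-nucleotide variant calls without a truth
set — tuning QUAL/DP filter thresholds, comparing callers, or reusing
archived call lists — who wants a quantitative answer to "what fraction
of these calls is real?" instead of the rule-of-thumb "Ti/Tv should be
about 2 (WGS) or 3 (WES)". The package also provides the machinery to
*build* such a model from gold-standard samples (e.g. NA12878): a
validation engine that counts TP/FP against a truth set, VCF/BED
statistics extraction, and a synthetic-data generator so the whole
pipeline is testable offline.

## The model

A call list of size N is N binary trials; the TP count Y is modelled
Beta-binomially to absorb the overdispersion a plain Binomial cannot:

    E[Y] = Nμ,   Var[Y] = Nμ(1−μ)(1+Nσ)/(1+σ)

with α = μ/σ, β = (1−μ)/σ the Beta shapes and σ = 0 the Binomial
limit. Both parameters depend on call-set covariates — Ti/Tv, Het/Hom,
MedDp, DpLt5 and a WES indicator, centered, with squares and
interactions:

    μ = exp(x′β)/(1+exp(x′β)),   σ = exp(z′γ)

A model is "(p, q)" by the lengths of β and γ. Fitting is exact joint
maximum likelihood; model choice uses Wald-p-driven backward
elimination with an AIC stopping rule, Akaike weights, and a Box-Cox
scan of the dispersion link. The 95% prediction interval for the
observed PPV of a new call set is μ̂ ± 1.96·sd(Y/N), truncated to
[0, 1], with leave-one-out coverage as the calibration check.
See `docs/methods.md` for the full account.

## Worked example

Fit the selected (11, 6) model on a training table (here a synthetic
one with the statistical structure of a ~500-call-list gold-standard
study) and predict the PPV of a new WES call list:

```python
import snvppv as sp

table = sp.simulate_training_table(sp.default_config(seed=1))
model = sp.fit(table, sp.named_spec("m11_6"))
print((model.spec.p, model.spec.q), round(model.aic, 2))
# (11, 6) 6136.86

print(model.summary().head(5).to_string(index=False))
# part          term  estimate  std_error    z_value      p_value
# mean   (Intercept)  5.006607   0.025598 195.588420 0.000000e+00
# mean wes_indicator -1.415238   0.028279 -50.045510 0.000000e+00
# mean          titv  5.168382   0.036615 141.153202 0.000000e+00
# mean        med_dp -0.019639   0.000497 -39.520906 0.000000e+00
# mean        dp_lt5 -1.634033   0.099316 -16.452812 8.006345e-61

stats = {"titv": 2.8, "hethom": 1.9, "med_dp": 55.0,
         "dp_lt5": 0.02, "wes_indicator": 1}
pi = sp.predict_interval(model, stats, 37627)
print(f"{pi.point:.4f} [{pi.lower:.4f}, {pi.upper:.4f}] {pi.length_pct:.2f}%")
# 0.9696 [0.9575, 0.9817] 2.42%
```

Reading: a 37,627-call exome list with Ti/Tv 2.8 and good depth is
estimated to be 97.0% true positives, and the *observed* PPV of such a
list should fall between 95.8% and 98.2% with 95% confidence — an
interval only 2.4 percentage points wide. The Ti/Tv coefficient (+5.17
on the logit scale per centered unit) quantifies the familiar fact that
false positives depress Ti/Tv.

The same flows are available from the shell:

```sh
snvppv stats calls.vcf --regions targets.bed --min-qual 30 --wes
snvppv validate --calls calls.vcf --truth truth.vcf --confident conf.bed
snvppv fit --table training.tsv --spec m11_6
snvppv loo --table training.tsv --spec m11_6 --restrict-above 0.95
snvppv select --table training.tsv --start-spec global_mean_18
snvppv lambda-scan --table training.tsv --spec m11_6
snvppv diagnose --table training.tsv --spec m11_6
snvppv simulate --n-obs 500 --seed 1 --out-table training.tsv
```

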