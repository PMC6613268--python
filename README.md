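# crossblup

Genomic prediction of **purebred (PB) sires for crossbred (CB) performance**,
with and without breed-of-origin of alleles (BOA), evaluated through
family-matched cross-validation.

## The problem

Pig and poultry breeding programs select purebred sires, but the product is a
crossbred animal — here a three-way cross **A(B×C)**: sires from a purebred
line A mated to F1 dams from two dam lines B and C. When the genetic
correlation between purebred and crossbred performance, *r*<sub>pc</sub>, is
below 1, a crossbred reference population may predict sires' crossbred merit
better than a purebred one. And because only half of a crossbred's alleles
descend from the sire line, a genomic relationship matrix (GRM) that tracks
the **breed of origin of each allele** can separate the sire-line signal from
dam-line noise.

`crossblup` provides every stage needed to study these questions without
proprietary data: a gene-drop simulator of three-way-cross populations with a
configurable *r*<sub>pc</sub>, the standard data-cleaning filters, the four
relevant relationship matrices, GBLUP/sire mixed models with EM-REML, and the
cross-validation scenario engine with reliability-weighted validation
statistics.

## The model

GEBV come from the univariate animal model

```
y = X b + L m + Z a + e,      a ~ N(0, G σ²ₐ),  m ~ N(0, I σ²ₘ),  e ~ N(0, I σ²ₑ)
```

with a combined batch×pen×sex×age fixed-effect class and a maternal
permanent-environment effect per dam. `G` is one of:

* **single-breed** VanRaden `G = MM′ / Σ 2pⱼ(1−pⱼ)`, `M` centred at `2pⱼ`;
* **multi-breed** block matrix with group-specific frequencies `p^PB`, `p^CB`
  and the geometric-mean denominator on the cross block;
* **BOA partial (sire line)** `G_BOA`: crossbred rows use only the allele
  inherited from line A, centred as `tⱼ − pⱼ` with `pⱼ` the sire-line allele
  frequency (pooled over sires' alleles and crossbreds' sire-origin alleles);
  the expected crossbred diagonal is 0.5;
* **dam-line partial**: the mirror image from dam-origin alleles, a probe of
  the predictive value of dam alleles.

Validation records are phenotypes corrected with a sire model
(`y_c = T ŝ + ê`). Sire GEBV are validated against crossbred offspring
averages with reliability weights `(¼ n h²_CB) / (1 + ¼(n−1) h²_CB)` and the
dispersion-bias regression doubled (an offspring average carries half the
sire's breeding value); crossbred GEBV are validated against individual
corrected records.

## Worked example

Simulate a small three-way-cross study (*r*<sub>pc</sub> = 0.8), run five
replicate crossbred subsets and compare individual-record validation with the
full G (`CB-I`) against the sire-line BOA matrix (`CB-I-BOA`):

```python
import crossblup as cb

config = cb.SimConfig(
    n_markers=600, n_qtl=200,
    n_sires=24, n_sires_both=20, n_sires_pb_only=1, n_sires_cb_only=3,
    n_pb_dams=80, n_cb_dams=160, n_dam_line_founders=60,
    n_pb_offspring=450, n_cb_offspring=800,
    traits=(cb.TraitSpec("BW7", h2_pb=0.09, h2_cb=0.18, r_pc=0.80),),
    seed=1,
)
results, dataset = cb.run_study(
    config, ["CB-I", "CB-I-BOA"], n_replicates=5, base_seed=1, h2_policy="animal"
)
print(cb.summarize_replicates(results).round(3).to_string(index=False))
print("win fraction CB-I over CB-I-BOA:",
      cb.win_fraction(results, "CB-I", "CB-I-BOA"))
```

prints

```
scenario trait  mean_correlation  sd_correlation  mean_bias  sd_bias  n_replicates
    CB-I   BW7             0.108           0.026      1.081    0.242             5
CB-I-BOA   BW7             0.016           0.054      0.364    1.210             5
win fraction CB-I over CB-I-BOA: 1.0
```

The full-G correlations beat the BOA ones in every replicate — not because
the sire GEBV are better, but because individual crossbred records retain a
dam genetic component that the dam alleles in the full G can predict. That
inflation is exactly why offspring-average validation (the `-A` scenarios) or
BOA-aware validation is preferred when comparing reference populations.

A command-line pipeline wraps the same steps
(`crossblup simulate/qc/run/summarize --config config.yaml ...`); every run
writes its resolved configuration next to its outputs.

## Layout

| module | contents |
| --- | --- |
| `crossblup.simulate` | line frequencies, gene drop, QTL effects, phenotypes |
| `crossblup.qc` | outlier / call-rate / Mendelian / MAF filters |
| `crossblup.grm` | the four relationship matrices |
| `crossblup.blup` | `GBLUP`, `SireModel`, EM-REML, Henderson equations |
| `crossblup.scenarios` | matched sampling, CV groups, weighted statistics |
| `crossblup.study` | replicate driver |
| `crossblup.cli` | `crossblup` command-line pipeline |

See `docs/methods.md` for modelling assumptions, numerical choices and
limitations.
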