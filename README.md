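# switchscan

Analysis toolkit for the **diet-switch** experimental design in *Drosophila*
dietary-restriction (DR) research: three fly cohorts — control food (CF),
restricted food (RF, chronic DR), and a cohort switched from CF to RF at the
day the cohorts' mortality trajectories separate (SF) — are profiled for gene
expression at closely spaced times after the switch, while their survival is
tracked daily. Genes whose expression in the SF cohort rapidly leaves the CF
level and settles at the RF level within the window in which SF mortality
drops to the RF trajectory are the strongest candidates for proximal
mediators of the DR longevity response.

The package is for quantitative biologists who want to analyze such designs
(or prototype them in simulation): it provides ground-truth simulators for
both the expression time course and the Gompertz survival cohorts, the
survival statistics (life tables, instantaneous hazards, log-rank tests,
mortality-switch detection), the differential-expression machinery, the
temporal-response classifier, and downstream gene-set and cross-study
comparisons.

## The statistics at the core

**Mortality.** Per-day hazard is estimated from the life table as
h(d) = −ln(1 − D/N) with deaths D and flies-at-risk N pooled over a centered
window. The switch day is the first day from which h_CF/h_RF ≥ 1.5 holds for
k consecutive days; post-switch convergence is the smallest lag L with
|ln(h_SF/h_RF)| ≤ ln(1 + tol) for k consecutive days from day
`switch_day + L`. Cohorts are compared with the standard log-rank test, and
"maximum lifespan" is the mean death day of the longest-lived 10 %.

**Expression.** For each gene, each cohort pair (RF vs CF, SF vs CF,
SF vs RF) is tested with a two-sided paired t-test, pairing per-time-point
means by time of collection. One Benjamini–Hochberg step-up is applied to
the *pooled* p-values of all genes × all three comparisons. With
S(·) = "significant at FDR 0.05", genes are classified:

| category | pattern (RFvCF, SFvCF, SFvRF) | meaning |
|---|---|---|
| I | S, S, ¬S | switching — SF left CF, matches RF |
| II | S, ¬S, S | refractory — SF pinned to its CF history |
| III | S, S, S | responsive but non-switching |
| IV | ¬S, S, – | deviating — responds to the switch, not the diet level |
| V | ¬S, ¬S, ¬S | null |
| VI–VIII | residual | non-responding / slow-partial / too variable |

Category I genes additionally get a switch-completion time (earliest sampled
hour from which the SF trajectory stays within 10 % of the CF→RF gap of the
RF level), used to curate fast switchers (complete by 8 h).

**Set statistics.** Over-representation of up/down gene lists in GMT gene
sets is the upper-tail hypergeometric test with BH correction per
(category, direction) family; cross-study comparison reports overlap
significance and the same/opposite direction split of shared genes.

## Worked example

```python
import switchscan as ss

# simulate a 500-gene, 12-time-point, 3-replicate, 3-cohort time course
cfg = ss.ExprSimConfig(n_genes=500, delta=2.0, sigma=0.25, seed=1)
matrix, truth = ss.generate_expression(cfg)
model = ss.SwitchCategorizer(fdr=0.05).fit(matrix)
print(model.summary_.to_string(index=False))
```

```
category  n_genes  n_down  n_up
       I       10       6     4
      II       12       5     7
     III       30      12    18
      IV        7       3     4
       V      439       0     0
      VI        0       0     0
     VII        2       0     0
    VIII        0       0     0
```

The simulator plants archetypes with known truth: here 10 fast switchers
were drawn and all 10 are recovered as Category I (6 down, 4 up — the
generator's default mix skews switching genes 2:1 down, as seen under
chronic DR); the 30 Category III genes are the responsive and slow/partial
archetypes, and the large Category V block is the diet-independent null.

```python
events, _ = ss.generate_cohorts(ss.CohortSimConfig(n_flies=3000, seed=1))
haz = {c: ss.hazard(ss.build_life_table(events, cohort=c), window=5)
       for c in ("CF", "RF", "SF")}
print("separation day:", ss.detect_separation(haz["CF"], haz["RF"], fold=1.5, k=3))
print("convergence lag:", ss.detect_convergence(haz["SF"], haz["RF"],
                                                switch_day=40, tol=0.25, k=2))
```

```
separation day: 1
convergence lag: 5
```

The simulated CF cohort runs at twice the RF hazard from day 1, so the
1.5-fold separation rule fires immediately; the switched cohort's hazard is
detected back on the RF trajectory 5 days after the switch in this replicate
(the generating lag is 3 days; the detected lag has a median of 3 across
replicates).

The same stages are available from the shell:

```bash
switchscan simulate-expr --seed 1 --out sim/
switchscan simulate-cohorts --seed 1 --out sim/
switchscan demog --events sim/events.tsv --fold 1.5 --k 3 --out demog/
switchscan diffexp --expr sim/expression.tsv --meta sim/metadata.tsv --out comparisons.tsv
switchscan categorize --comparisons comparisons.tsv --expr sim/expression.tsv \
    --meta sim/metadata.tsv --out cats/
switchscan run --config run.yaml        # full pipeline with a JSON+text report
```

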