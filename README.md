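# pupfast

Fasting-phase classification and subpopulation inference for Steller sea
lion (*Eumetopias jubatus*) pups from two plasma metabolites.

## The problem

While their dams forage at sea, otariid pups fast ashore and move through
predictable metabolic phases: glycogen use just after feeding (Phase I),
protein-sparing lipid catabolism (Phase II), and renewed protein
catabolism preceding starvation (Phase III).  Two cheap plasma markers
locate a pup on this continuum — blood urea nitrogen ([BUN], protein
catabolism) and β-hydroxybutyrate ([β-HBA], ketosis).  Classifying pups
sampled during routine captures turns archived plasma into a
retrospective maternal-attendance monitor: rookeries whose dams take
longer foraging trips show more pups deep in the fast.  That matters for
management, because subpopulations of this species have had sharply
different population trends for decades.

`pupfast` provides, for researchers in pinniped physiology and marine
mammal management:

- a **threshold classifier**: (BUN, β-HBA) → {Fed–I, II, II–III, III,
  Unclassified}, with cutpoints in an auditable YAML config, plus the
  Short/Long duration collapse and the body condition index
  BCI = mass / (−63.88 + 0.8966 · standard length);
- an **assay QC** layer: four-parameter logistic standard curves
  y = d + (a−d)/(1+(x/c)^b), a replicate CV ≤ 10% gate with one repeat
  assay, a two-stage ketometer screen around 0.3 mmol/L β-HBA, and
  hemolysis exclusion;
- a **cohort builder**: rookery → subpopulation/region/DPS mapping,
  the ≥5-pups-per-sampling-event rule, the before/after July-19
  attendance-shift check, category proportion tables, and validation
  against a-priori field-note expectations;
- an **inference battery** in the statsmodels Model/Results idiom: a
  binomial GLM of Short vs Long fasts,

  logit P(Long) = β₀ + f(BCI, subpopulation, sex, timing, interactions),

  with backward selection by likelihood-ratio tests, sex-corrected
  marginal means with 95% CIs, single-step (Tukey) all-pairs contrasts
  among the 12 subpopulations, Kruskal–Wallis + Dunn–Bonferroni rank
  tests on sampling-event proportions, and sex-ratio χ² tests;
- a **maternal-attendance simulator** generating cohorts with known
  ground truth (attendance cycles, hours fasted, true phase), so every
  stage is testable without field data.

## Worked example

```python
import pupfast as pf
from pupfast.pipeline import run_analysis

cohort = pf.simulate_cohort(pf.default_design(seed=1))   # 1528 pups, ground truth attached
raw = cohort.drop(columns=["hours_fasted", "true_phase"])  # field-data shape
bundle = run_analysis(raw)

mm = bundle["marginal_means"].set_index("subpopulation")
for sub in ("eastern Aleutian Islands", "western Aleutian Islands",
            "southern Southeast Alaska"):
    r = mm.loc[sub]
    print(f"{sub:28s} {r['estimate']:.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f})")
```

prints

```
eastern Aleutian Islands     0.111 (0.066-0.181)
western Aleutian Islands     0.259 (0.146-0.418)
southern Southeast Alaska    0.359 (0.299-0.424)
```

— the model-estimated proportion of pups caught in Long-duration fasts
per subpopulation, averaged over sex, with 95% confidence intervals: in
this simulated cohort roughly one pup in nine in the eastern Aleutians is
deep into a fast, against one in three in the western Aleutians and
southern Southeast Alaska, the pattern the stock design builds in.  The
selection trace shows the null terms leaving the model (`bundle
["selection_trace"]`), and `bundle["contrasts"]` holds all 66 pairwise
subpopulation contrasts with family-wise adjusted p-values:

```
level_i            level_j                    estimate    p_adj
Kuril Islands      central Aleutian Islands   -1.393      0.0013
Kuril Islands      southern Southeast Alaska  -1.491      0.0000
...
```

(log-odds differences; negative means the left subpopulation has the
lower Long-fast proportion).

The same pipeline is scriptable from the shell:

```sh
pupfast simulate --seed 1 --out run/
pupfast analyze --input run/cohort.csv --out run/results/
pupfast report --bundle run/results/
```

`pupfast qc` reduces long-format plate CSVs through the standard-curve
and CV gates, and `pupfast classify` appends category/duration/BCI
columns to any record table with `bun_mmol_l` and `bhba_mmol_l` columns.

## Layout

```
src/pupfast/classify.py    threshold classifier, duration collapse, BCI
src/pupfast/assay.py       4PL curves, CV gate, ketometer screen
src/pupfast/attendance.py  attendance + metabolite simulator
src/pupfast/cohort.py      selection rules, geography, proportion tables
src/pupfast/ranktests.py   Kruskal–Wallis, Dunn, χ² tests
src/pupfast/model.py       FastingDurationModel / FastingDurationResults
src/pupfast/pipeline.py    end-to-end orchestration
src/pupfast/cli.py         simulate / qc / classify / analyze / report
src/pupfast/data/          thresholds.yaml, rookeries.csv (versioned configs)
docs/methods.md            model assumptions, defaults and their rationale
```
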