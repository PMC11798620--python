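# triagesim

Simulation and comparison of **scarce-resource-allocation (SRA) protocols** —
the crisis-standards-of-care rule sets that decide which critically ill
patients receive ventilators when demand exceeds supply.

During the early COVID-19 pandemic, US states and hospital systems published
divergent triage protocols: all score illness severity with the Sequential
Organ Failure Assessment (SOFA, 0–24), but they differ in exclusion criteria,
age and pregnancy weighting, frontline-worker treatment, and how ties at the
capacity boundary are broken (first-come-first-served vs. randomized
lottery vs. nothing at all). `triagesim` encodes six such protocols — labelled
MD, PA, FL, NY, CA and NE after their issuing state or institution — as
declarative rule sets, applies them to a common cohort of nine mock
critically ill patients competing for three remaining ventilators, and
quantifies how much the *protocol*, rather than the patient, determines who
is treated.

The package is aimed at health-policy and medical-ethics researchers who want
a reproducible, auditable implementation of rule-based triage rather than a
spreadsheet exercise.

## The model

For a patient with SOFA total $s$, age $a$, comorbidity class $c$ and
pregnancy status $g$, a protocol assigns a priority score

$$\mathrm{score} = \mathrm{band}_{\mathrm{SOFA}}(s) + \mathrm{pts}(c) + \mathrm{band}_{\mathrm{age}}(a) + \beta_{\mathrm{preg}}\,\mathbb{1}[g],$$

with **lower = higher priority**, after exclusion screening (comorbidity
lists and/or a SOFA cutoff) and any frontline-worker exemption. Patients are
grouped by equal score; groups are served in order until capacity $k$ is
exhausted; a group straddling the boundary is resolved by the protocol's
ordered tie-break chain (younger age → frontline → arrival order → seeded
lottery). Outcomes are four-valued: allocated (`***`), tied-but-lost (`**`),
qualified-but-undetermined (`*`, for protocols with no tie-break mechanism),
and not allocated / excluded (`O`).

The source protocol documents publish qualitative rules, not point tables;
the shipped configurations were reconstructed by an exhaustive calibration
search (`triagesim.calibrate`) constrained to reproduce the reference
allocation outcomes of the nine-patient scenario. See `docs/methods.md`.

## Worked example

```python
from triagesim import (ScenarioConfig, build_matrix, concordance,
                       load_fixture_cohort, load_protocol, list_protocols)

cohort = load_fixture_cohort()                      # nine mock patients
rulesets = [load_protocol(p) for p in list_protocols()]
scenario = ScenarioConfig(n_ventilators=3, rng_seed=0)
matrix = build_matrix(cohort, rulesets, scenario)
print(matrix.table)
```

```
         age     sex  sofa   MD   PA   FL   NY   CA NE
patient
1         45  female    14    O    O    O    O  ***  O
2         65    male    10    O    O    O    O    O  O
3         27  female    10  ***    O    O    O  ***  O
4         50    male     6    O  ***  ***   **    O  *
5         92    male     4   **  ***  ***  ***    O  *
6         40    male     8  ***    O    O    O    O  *
7         28  female     5  ***  ***  ***  ***  ***  *
8         57    male     2    O    O    O  ***    O  *
9         75  female     8    O    O    O    O    O  *
```

Reading the grid: patient 7 (28 F, SOFA 5, no comorbidity) receives a
ventilator under five of the six protocols, while patient 2 (65 M, SOFA 10,
end-stage renal disease) receives one under none. The pregnant patient (3)
is treated only where pregnancy subtracts priority points (MD, CA); the
nurse (1) only where frontline workers are exempted from scoring (CA). NE
specifies no tie-break at all, so its five qualifying patients are left
undetermined (`*`) and no ventilator is assigned.

```python
report = concordance(matrix)
print(report.n_vector_identical, report.set_identical_pairs)
# 0 (('PA', 'FL'),)
```

No two protocols produce the same full outcome vector on this cohort
(PA and FL allocate to the same three patients, but for different reasons —
exclusion vs. outranking — which the status-level comparison distinguishes).

A CLI wraps the same pipeline:

```bash
triagesim simulate --cohort fixture --protocols all --ventilators 3 --seed 17 --out out/
triagesim chance --protocols NY --randomize arrival --chance-reps 10000 --out out/
triagesim calibrate --grid grid.yaml --target target.yaml --out out/
triagesim generate-cohort --n 100 --seed 1 --out cohort.csv
```

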