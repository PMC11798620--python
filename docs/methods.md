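# Methods

## Scenario and model

The package simulates a single allocation round: a hospital with 30
ventilators has 3 left, and 9 critically ill adults need one. Six triage
protocols (MD, PA, FL, NY, CA, NE) are applied independently to the same
cohort; each produces, per patient, one of five statuses — `allocated`,
`tied_lost`, `qualified_undetermined`, `not_allocated`, `excluded` —
rendered in comparison tables as `***`, `**`, `*`, `O`, `O`.

Evaluation of one protocol proceeds in four stages:

1. **Exclusion screening.** A patient is excluded if their comorbidity is on
   the protocol's exclusion list, if their SOFA total crosses the protocol's
   exclusion cutoff (the comparator — strict `>` vs. inclusive `>=` — is part
   of the configuration, never hard-coded), or, for qualification-only
   protocols, if they fail the qualification cutoff (`SOFA < cutoff`).
2. **Frontline exemption.** Under an `exemption` policy (CA), healthcare
   workers and first responders bypass scoring entirely and are served
   first, consuming capacity.
3. **Scoring.** Eligible patients receive
   `SOFA-band points + comorbidity points + age-band points + pregnancy modifier`.
   Lower scores mean higher priority, uniformly; source protocols oriented
   the other way are re-oriented in their config files (one comparator
   package-wide, fewer sign bugs). `sofa_bands` may instead be `"raw"` (the
   SOFA total itself is the score — FL) or absent (no severity scoring at
   all — NE, whose qualifiers form one undifferentiated group scored 0).
   Every term is recorded in an audit trace, and an invariant ties the score
   to the sum of its own trace entries.
4. **Capacity-constrained allocation.** Priority groups are served in
   ascending-score order. A group that fits remaining capacity is allocated
   wholly; a straddling group is split by the tie-break chain, applied
   stepwise so each later step only breaks ties surviving earlier steps:
   `younger_age` (ascending age), `frontline` (frontline first), `fcfs`
   (ascending arrival position), `lottery` (uniform sampling without
   replacement from the surviving tied set, one seeded generator per
   protocol run). Losers at the boundary are `tied_lost`. If the chain is
   empty or exhausted with the tie unresolved, the whole straddling group
   becomes `qualified_undetermined`, no ventilator is assigned from it, and
   no lower group may leapfrog it.

A protocol with neither severity scoring nor a tie-break chain (NE) gives no
basis for choosing among qualifiers, so *all* of them are
`qualified_undetermined` and none is served, at any capacity. We read the
undetermined outcome as "allocation undefined" rather than "implicit
lottery"; `allocate(..., resolve_unscored_by_lottery=True)` flips that
reading for sensitivity analysis.

## Shipped protocol reconstructions

The six source documents are summarized qualitatively in the record this
scenario derives from (which factors each protocol uses, its SOFA cutoffs,
its tie-break style); exact point tables are not published. The shipped
configurations are therefore **reconstructions**: for each protocol, a
bounded grid of candidate parameters was searched exhaustively
(`triagesim.calibrate`) under the constraint that simulated outcomes match
the reference allocation grid for the eight patients it reports. Decisions
worth flagging:

- **MD** excludes end-stage renal disease, late-stage multiple sclerosis and
  NYHA-IV heart failure plus SOFA > 14, but *not* metastatic cancer, even
  though qualitative summaries list cancer among commonly cited exclusions:
  the reference outcomes allocate the metastatic-cancer patient under MD,
  and the calibration follows the outcomes. The conflict is surfaced, not
  resolved.
- **PA** treats dementia as a non-qualifying comorbidity (0 points) while
  other severe life-limiting conditions add +4; this is required for the
  92-year-old dementia patient's allocation under PA. Dementia's default
  severity class is severe/life-limiting in the shared vocabulary; the PA
  override lives in that protocol's config.
- **NY**'s two bands (SOFA ≤ 7, 8–11) plus exclusion above 11 are the
  minimal structure consistent with its outcomes; its four-way top-group tie
  at the boundary is what makes arrival order decisive there.
- **NE**'s qualification cutoff is genuinely under-determined: cutoffs 9 and
  10 reproduce the reference column identically because no cohort patient
  has SOFA 9. We ship 10 (the round number consistent with the other
  protocols' use of 10 as a severity landmark); the calibration search
  reports both, by design — non-uniqueness is surfaced as a multi-element
  result set.
- **Arrival order.** The scenario narrative gives no arrival times. The
  default order (ids 1,2,3,5,6,7,8,9,4 — patient 4 last) is the package's
  assumption, chosen so first-come-first-served tie-breaking reproduces the
  reference outcomes; it is configurable per scenario
  (`ScenarioConfig.arrival_order`), and `chance_analysis(randomize="arrival")
  ` quantifies how much hangs on it (each of NY's four tied patients wins
  with probability 3/4 under a random order).
- **Patient 9** (75 F, NYHA-IV heart failure, SOFA 8) is part of the cohort
  but her outcomes are unreported in the reference grid; she is simulated
  normally and excluded from golden comparisons rather than guessed.
- Protocol concordance is reported at two levels because they genuinely
  differ: PA and FL allocate to the same three patients (set-level
  identity) yet their full status vectors differ (PA never excludes; FL
  screens five patients out). The headline "no two protocols agree" holds at
  the status-vector level.

## SOFA calculator

The SOFA total (0–24) is the sum of six organ-system subscores (0–4):
respiration (PaO₂/FiO₂, mmHg), coagulation (platelets, ×10³/µL), liver
(bilirubin, mg/dL), cardiovascular (MAP, mmHg, with vasopressor dose tiers in
µg/kg/min), CNS (Glasgow Coma Scale) and renal (creatinine, mg/dL, with
daily urine output; the worse of the two governs). Thresholds follow the
standard published table and ship as a versioned data file so another
dialect can be swapped in. Scores 3–4 for respiration conventionally assume
ventilatory support; the calculator scores the ratio alone and leaves that
qualifier to the caller. The cohort patients carry SOFA totals directly
(their underlying vitals are not part of the scenario), so the calculator is
validated against the threshold table and its monotonicity/range properties
rather than against the cohort.

## Synthetic cohort generator

`generate_cohort` emulates the fixture's structure for power and property
testing: adult ages uniform on 27–92, both sexes (default 50/50), SOFA
totals uniform on 0–24, a seven-code comorbidity vocabulary with benign
histories dominant (prevalences 0.50/0.20/0.06×5), pregnancy at rate 0.10
among females aged 18–45, frontline occupation at rate 0.20, low-SES flag at
0.10. These defaults are chosen to resemble a plausible crisis-admission
case mix; they are not fitted to any empirical distribution. The generator
does **not** model correlated physiology (SOFA independent of age and
comorbidity), multi-morbidity, arrival-time mechanisms, or pediatric
patients — so passing property tests demonstrate rule-engine correctness
under the stated invariants, not realism of any particular case mix.

## Numerical and design choices

- All randomness flows through `numpy` generators seeded from the scenario
  seed; `build_matrix` spawns one child stream per protocol so results are
  independent of protocol order and reproducible bit-for-bit.
- Monte-Carlo chance analysis defaults to 10,000 replicates with binomial
  standard errors `sqrt(p(1-p)/n)`; the lottery oracle test compares the
  empirical allocation probability of a 4-way tie for 3 units against the
  exact combinatorial value 3/4 within three standard errors.
- Calibration is plain enumeration with a configurable cap (10⁶ points):
  no pruning, so the oracle is trivially trustworthy and completeness over
  the grid is by construction.
- Band lists must be disjoint and contiguous at load time; a patient falling
  outside band coverage is a configuration error at evaluation time, not a
  silent default.
- Ties *below* the capacity boundary are never marked `tied_lost`; the
  status applies only where capacity actually bites.
- Problem sizes in the test suite (cohorts of ≤ 40 for property tests,
  2,000 for distribution checks, 10,000 Monte-Carlo replicates) were chosen
  to give three-standard-error resolution on the quantities checked while
  keeping the suite fast.

## Known limitations

Single resource type, single allocation round: no re-triage, ventilator
withdrawal, or patient death/recovery dynamics. Single-valued comorbidity
per patient. The six rule sets are calibrated reconstructions consistent
with the reference outcomes, not transcriptions of the source documents;
where the reference under-determines a parameter, the shipped value is one
member of the reported solution set.
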