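# delphiscore

Delphi consensus analysis and content validity for clinical checklist
instruments — built around a nursing score for home palliative care.

Home palliative-care teams need a defensible way to decide how much nursing
attention a patient requires. One approach is a checklist score: a set of
care-need categories (parenteral access, tubes, wound care, hygiene,
delirium, social/family issues), each worth a fixed number of points, with a
patient scoring the sum of points over every category in which at least one
problem is present. Such an instrument is only as good as the expert
consensus behind it, so `delphiscore` packages both the instrument *and* the
validation machinery:

- **`delphiscore.instrument`** — checklist definition and patient scoring.
  The bundled default is a seven-category nursing score whose category
  points (5, 1, 1, 2.5, 2, 2.5, 2) sum to a maximum of 16; a category
  contributes its points once no matter how many of its problems apply.
- **`delphiscore.consensus`** — per-item Likert summaries (median, P25–P75
  by linear interpolation between closest order statistics, agreement
  percentage rounded half-up) and the consensus rule *at least 80 % of
  respondents rating the item ≥ 7 on a 1–10 scale*, evaluated on exact
  fractions so boundary panels (4 of 5) count.
- **`delphiscore.aiken`** — Aiken's content-validity coefficient
  `V = Σ(rᵢ − l) / (n (c − 1))` for `n` judges on a `c`-category scale with
  lowest value `l`, plus an **exact** right-tail p-value under the null that
  every judge rates uniformly at random, computed by integer convolution of
  the discrete-uniform distribution (a normal approximation is available for
  very large panels).
- **`delphiscore.delphi`** — the multi-round engine: items reaching
  consensus are settled and never re-rated, the rest carry over; after the
  configured maximum number of rounds (default 4), stagnant items are marked
  for exclusion. Aggregate-only feedback reports and panel-roster summaries
  included.
- **`delphiscore.panelsim`** — a seeded synthetic expert-panel generator
  (mixture rater model with closed-form endorsement probabilities) so every
  pipeline stage is testable without survey data.

## Worked example

```python
from delphiscore import (PanelModel, simulate_panel, run_round,
                         feedback_report, aiken_table)

matrix = simulate_panel(PanelModel(agreement=0.9, seed=11))
result = run_round(matrix)
print(feedback_report(result))
```

```
## Delphi round 1

| Item | Median (P25–P75) | Agreement | Status |
| --- | --- | --- | --- |
| complex_wound_care | 8 (7.5–9) | 18 (94.7%) | consensus |
| delirium | 7 (7–8) | 16 (84.2%) | consensus |
| hygiene | 9 (8–10) | 19 (100%) | consensus |
| parenteral_access | 8 (7–9) | 17 (89.5%) | consensus |
| simple_wound_care | 9 (7.5–10) | 18 (94.7%) | consensus |
| social_family_issues | 8 (7–8) | 18 (94.7%) | consensus |
| tubes | 8 (8–9) | 19 (100%) | consensus |
```

Every item was endorsed by at least 16 of the 19 simulated panellists
(84.2 % ≥ the 80 % rule), so all seven settle in round one. The same
matrix yields a validity table — `aiken_table(matrix)` prints, per item,
the two-decimal V and its exact p-value (rendered `<0.001` below that
threshold):

```
             item_id  n_raters  v_aiken p_value
  complex_wound_care        19     0.80  <0.001
            delirium        19     0.70   0.004
             hygiene        19     0.87  <0.001
   ...
```

Scoring a patient against the bundled instrument:

```python
from delphiscore import default_instrument, PatientAssessment, score_patient

inst = default_instrument()
a = PatientAssessment("patient-07",
                      ["subcutaneous_hydration", "urinary_catheter", "delirium"])
print(score_patient(a, inst))   # 8.5  (= 5 parenteral + 1 tubes + 2.5 delirium)
```

The same workflows are available from the shell via the `delphiscore`
command (`score`, `aiken`, `round`, `validate`, `roster`, `simulate`); run
`delphiscore --help` for details.

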