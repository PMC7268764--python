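# acangle

Anterior chamber angle (ACA) morphometry and ordinal grading from
anterior-segment OCT boundary segmentations.

Angle-closure glaucoma risk is judged clinically by gonioscopy, a contact
examination that grades each quadrant of the ACA (Scheie grades, collapsed
here to small / moderate / large angle: SA < MA < LA).  AS-OCT images the
same anatomy without contact: given segmented boundary polylines (posterior
cornea / inner corneoscleral wall, anterior iris) and a scleral spur
landmark per side of each radial B-scan, `acangle` computes the standard
angle parameters and a tangent-line parameter that summarizes the whole
iris profile, then grades all 32 sections of an eye:

* **AODSS / AOD750** — angle opening distance: perpendicular distance from
  the inner wall to the iris, at the scleral spur and 750 µm anterior to it;
* **TISA750** — trabecular–iris space area between the two casts;
* **LID** — light intersection distance: the line from the corneal
  endothelial apex grazing the iris vertex is extended to the wall; LID is
  the signed distance from the spur to that intersection (negative =
  anterior = narrower angle).

Grading uses a proportional-odds model on the cumulative logits

    Q_SA    = logit(P_SA)        = α₁ − β·LID
    Q_SA+MA = logit(P_SA + P_MA) = α₂ − β·LID

with a built-in reference model (α₁ = −2.111, α₂ = 0.019, β = 10.231); each
11.25° section receives the grade of highest probability, and quadrants are
graded from the quadrant-mean predictor.  The package also provides the full
validation toolkit (confusion matrix and correct rates, quadratic-weighted
kappa, Mann–Whitney AUC, one-way ANOVA, Bland–Altman limits of agreement),
maximum-likelihood fitting (ordinal and binary open/closed, with stepwise
predictor selection), and a synthetic anterior-segment generator with exact
closed-form ground truth so the whole pipeline is testable without clinical
data.

## Worked example

Simulate one right eye with a narrow superior quadrant, a moderate nasal
quadrant and wide inferior/temporal quadrants, then measure, grade and
compare against the generator's ground truth:

```sh
acangle simulate cohort --n-eyes 1 --seed 5 --out cohort \
    --preset S=narrow --preset N=moderate --preset I=wide --preset T=wide
acangle measure  --input cohort/eye000.json --out metrics.csv
acangle grade    --metrics metrics.csv --out grades.csv --map-json map.json
acangle evaluate --actual cohort/truth.csv --predicted grades.csv --out report.json
```

which prints

```
wrote 1 eye(s) to cohort
eye000: measured 32 sections, 32 complete
graded 1 eye(s) -> grades.csv
overall correct rate 100.0%, quadratic kappa 1.000
```

`metrics.csv` holds one row per section, e.g.

```
eye_id,meridian_deg,side,section_index,aodss_mm,aod750_mm,tisa750_mm2,lid_mm,status
eye000,0.0,right,0,0.0603,0.4272,0.1799,0.1005,ok
```

(a temporal section: LID +0.10 mm, i.e. the grazing ray lands posterior to
the spur — a wide angle), and `map.json` carries the eye-level map

```
quadrants:   {"S": "SA", "I": "LA", "N": "MA", "T": "LA"}
proportions: {"SA": 0.25, "MA": 0.25, "LA": 0.5}
```

— the superior quadrant grades small-angle, the nasal moderate, and 25% of
the circumference is small-angle at section resolution.  The same library
calls are available in Python (`acangle.measure_section`,
`acangle.build_grade_map`, `acangle.fit_ordered_logit`, ...).

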