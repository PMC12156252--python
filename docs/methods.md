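# Methods

`popsono` implements a fully automated pipeline for diagnosing pelvic organ
prolapse (POP) from dynamic two-dimensional transperineal ultrasound of the
midsagittal plane. The pipeline assumes the video has already been
segmented: for each of eight pelvic structures (pubis, urethra, bladder,
vagina, uterus, anus, rectum, levator ani) and each frame, a segmentation
network supplies a *confidence map* — per-pixel certainty in [0, 1] that
the pixel belongs to that organ. Everything downstream of segmentation is
implemented here; the segmentation network itself is a pluggable input, and
a scene simulator stands in for it so the pipeline can be exercised,
tested, and audited end to end without clinical data.

## Diagnostic criteria

Ground truth follows the standard sonographic mm-threshold criteria,
measured during the Valsalva maneuver relative to the posterior-inferior
edge of the pubic symphysis:

| pathology | criterion |
|---|---|
| cystocele | bladder descends ≥ 10 mm below the landmark |
| cystourethrocele | cystocele + urethra descends ≥ 10 mm |
| uterine prolapse | pubis–fundus distance shrinks ≥ 15 mm from rest |
| cervical elongation | that shrinkage < 15 mm while the cervix descends ≥ 15 mm |
| rectocele | rectum descends ≥ 15 mm, with anterior rectal wall herniation |
| enterocele | enterocele region descends ≥ 15 mm, with abdominal content anterior to the anorectal angle |
| any prolapse | OR of the six |

Thresholds are inclusive (exactly 10 mm is positive). Herniation and
abdominal-content findings are qualitative and enter the simulator as
boolean flags. No quantitative sonographic criterion exists for
cystourethrocele in isolation; we operationalise the "urethral
involvement" component as urethral descent past the same 10 mm landmark
offset that defines the bladder criterion. The orientation of the
"descent relative to the landmark" measurement is taken along the image
vertical (raster rows increase caudally), and the pubis–fundus distance is
likewise the vertical separation; with a probe-fixed pubis this makes a
descent of *d* mm reduce the pubis–fundus distance by exactly *d* mm.

## Scene simulator

Each organ is an axis-aligned ellipse in a 64 mm × 64 mm midsagittal field
of view (128 × 128 px at the default 0.5 mm/px). Frame 0 is the rest
configuration; organs ease toward their Valsalva positions along a
smoothstep ramp with per-frame Gaussian jitter (σ = 1 px) on top, so
descent is monotone in trend but noisy frame to frame. The pubis is
probe-fixed: constant and jitter-free, since it anchors the landmark.
Video length is drawn uniformly from 100–200 frames, matching typical
Valsalva clip durations.

Pathology profiles specify target values for the *measured* diagnostic
quantities; the simulator solves for the required displacement, so the
measured descent matches the profile within jitter (≈ ±1 mm). The cohort
generator draws pathological magnitudes uniformly in 1.5–2.0× the
diagnostic threshold — unambiguous disease, well clear of the decision
boundary — while healthy organs get 1–3 mm of physiological descent.
Two realism couplings matter:

* **Co-descent.** In a prolapse patient, organs not themselves prolapsed
  still descend by 0.25× the largest pathological descent (generalised
  pelvic floor laxity). Without this, records from uninvolved organs would
  carry no disease signal and the patient-level majority vote — which
  pools all organs' records — could not work for focal pathologies.
* **Urethral fixation.** The urethra is excluded from co-descent (it is
  held by the pubourethral ligaments); otherwise every cystocele would
  mechanically satisfy the cystourethrocele rule.

Cohort composition: a patient has some prolapse with probability 99/188;
conditional on that, pathology flags are drawn at referral-population
rates (cystocele 67/99, uterine prolapse 41/99, cervical elongation 36/58
among non-uterine patients, rectocele 24/99, enterocele 9/99, and
cystourethrocele 13/67 as a subset of cystocele). Sampling cervical
elongation only among non-uterine patients and cystourethrocele only
within cystocele keeps expected label totals equal to the target rates
despite the definitional implications between labels.

Confidence maps emulate a segmentation network trained exclusively on
healthy anatomy, used as an anomaly detector: confidence in an organ
degrades as the organ departs from where the network learned to expect it.
Rendering is a smoothstep sigmoid ramp of approximate signed distance to
the ellipse boundary (edge softness 1.5 px), saturating at

    peak = healthy_peak · (1 − degradation · min(1, displacement_mm / 30))

with `healthy_peak` = 0.95 and `degradation` = 0.5 by default; clipped
additive Gaussian speckle (σ = 0.02) is added. The smoothstep (rather
than a logistic) makes the interior saturate *exactly* at the peak, which
keeps the zero-displacement contract exact. A consequence of the
degradation model: beyond ≈ 28 mm displacement the peak falls below the
0.5 region threshold and the organ vanishes from its own region — the
network "loses" a grossly displaced organ, which is precisely the anomaly
signal, and the feature pipeline treats it as an absent organ.

What the simulator does **not** emulate: speckle statistics and
attenuation physics of real ultrasound, probe motion, organ shape change
other than uterine elongation, oblique descent directions, levator
avulsion, and segmentation failure modes unrelated to displacement.
Passing the recovery tests therefore shows the pipeline recovers labels
when the anomaly signal is present in position and confidence; it does not
certify performance on real clinical video.

## Feature engineering

Per frame and organ, 17 descriptors: mean/std/max/min of confidence over
all pixels (4) and over the organ region — pixels with confidence
strictly > 0.5 — (4), plus region geometry: centroid row/col, pixel area,
bounding-box width/height, and the four bounding-box corner coordinates
(9). Coordinates are 0-based raster (row, col); bounding-box extents are
inclusive (max − min + 1); centroids are unweighted; standard deviations
use the population convention (divide by n). An empty region makes the 13
region-dependent descriptors NaN.

Videos are cut into 60-frame windows advancing by 30 (half overlap); only
full windows are kept, so a 180-frame video yields 5 windows and a
< 60-frame video none. Each descriptor is aggregated over the window with
(mean, std, max, min) *over the frames where the organ is present*,
giving 68 = 17 × 4 variables per (organ, window) record; a record for an
organ never present in the window is all-NaN. With the organ indicator
this is the 69-column learning table; one row per (window, organ), so a
cohort totalling 677 windows gives exactly 5416 rows. NaNs are propagated
to the learner, which supports missing values natively.

## Modeling

One XGBoost binary classifier per target (7 targets: the six pathologies
plus "any prolapse"), each trained independently on the records. The
organ indicator enters as an integer code (fixed vocabulary order).
Positive records are weighted by `|Neg| / |Pos|` computed on the training
records, equalising the weighted class masses.

The patient-level split is 68% / 32% by default (rounded; exact set sizes
can be pinned). Hyperparameters are chosen by randomized search
(default 25 candidates; the pipeline default is 10 and the shipped
experiments use 6 — a size at which the search already saturates on the
synthetic task) over standard GBM ranges: max depth 2–8, learning rate
log-uniform 0.01–0.3, 50–500 rounds, row/column subsampling 0.5–1.0, L2
regularisation 0–10. Candidates are scored by mean record-level average
precision over grouped 5-fold cross-validation: patients are shuffled and
split into 5 blocks of near-equal patient count, so no patient's records
straddle folds (asserted at runtime). Folds whose validation part has no
positive record are skipped (AP is undefined there); per-fold positive
weights are recomputed on each fold's training part. The winner is refit
on the full training table.

Patient-level diagnosis: each of the patient's records (typically
4–5 windows × 8 organs) is scored, thresholded at 0.5, and the majority
call wins; an exact tie resolves positive, favouring recall. All
randomness — cohort sampling, split, fold assignment, candidate sampling,
booster seed — derives from one master seed, and identical config + seed
reproduces identical features, chosen hyperparameters and report.

## Evaluation

Patient-level accuracy, precision, recall and F1 in percent, plus the
expert-agreement fraction k/n (identical to accuracy by construction) with
a 95% Wald interval: z = 1.96, clipped to [0, 100], reported to one
decimal, computed from the agreement proportion rounded to one decimal
percentage point — the convention under which published tabulations of
this evaluation reproduce. Precision is undefined when no positive call
was made, recall when no positive patient exists, and F1 whenever either
is undefined or zero; undefined values render as "-".

### Behaviour of the patient vote for organ-specific pathologies

The majority vote pools the records of *all* organs. For "any prolapse"
this is ideal: every organ of a prolapse patient carries some anomaly
signal (co-descent, degraded confidence). For organ-specific targets it
creates a characteristic asymmetry: the records of a cystocele patient's
seven uninvolved organs are statistically indistinguishable from records
of patients with other prolapse types, so the record classifier scores
any "generic prolapse" record near the conditional rate of that pathology
among prolapse patients — above the 0.5 cut for a common pathology like
cystocele, especially with the positive-class weighting applied. The vote
then over-calls the pathology on prolapse patients of other types: recall
is perfect, and accuracy is limited by false positives (in the shipped
three-seed recovery experiment, cystocele holdout accuracy averages
≈ 0.83 with recall 1.00 on every seed). Rare pathologies sit on the other
side of the same mechanism and lose recall instead. Voting only over the
target organ's records, or modelling pathologies jointly, would address
this; both are out of scope here, and the pathologies are deliberately
modelled independently.

## Numerical and degenerate-input conventions

* Region membership is strictly `> 0.5`; a pixel at exactly 0.5 is out.
* Exact-threshold descents are positive (`>=` comparisons in the rules).
* Organs whose ellipse centre leaves the frame are marked not visible and
  render as zero maps.
* A cohort needs ≥ 2 patients (to be splittable) and grouped CV needs ≥ 5
  patients in training; targets that are single-class in the training
  cohort are skipped by the pipeline with a logged warning.
* Model bundles persist the raw booster as JSON plus a metadata sidecar
  (hyperparameters, positive weight, seeds, feature names).

## Problem sizes in the shipped experiments

The recovery experiments simulate 150-patient cohorts (≈ 4 000–4 300
records after windowing) and evaluate on the held-out 32%, averaged over
three master seeds; the demo pipeline configuration uses 40 patients.
These sizes give stable estimates for the binary any-prolapse and
cystocele endpoints while keeping a full run in the minutes range on a
single CPU.
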