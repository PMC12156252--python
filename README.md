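# popsono

Automated diagnosis of pelvic organ prolapse (POP) from dynamic
two-dimensional transperineal ultrasound of the midsagittal plane.

Pelvic organ prolapse — descent of the bladder, uterus, rectum or bowel
into the vagina during straining — is conventionally staged by clinical
examination and quantified on ultrasound by manual mm measurements taken
during a Valsalva maneuver, relative to the posterior-inferior edge of the
pubic symphysis (e.g. cystocele: bladder descent ≥ 10 mm; uterine
prolapse: ≥ 15 mm loss of pubis–fundus distance). `popsono` implements the
machine-learning side of a fully automated alternative, for researchers in
ultrasound image analysis and pelvic floor medicine:

1. **Input contract** — per organ and per frame, a segmentation network
   emits a confidence map `C ∈ [0,1]^{128×128}` for eight structures
   (pubis, urethra, bladder, vagina, uterus, anus, rectum, levator ani).
   The network is a pluggable upstream component; a built-in Valsalva
   scene simulator reproduces its output contract (including the anomaly
   effect: confidence degrades for organs far from their healthy
   position) together with mm-criterion ground-truth labels.
2. **Feature engineering** — 17 per-frame descriptors per organ
   (confidence statistics over the frame and over the region `C > 0.5`;
   region centroid, area, bounding box), aggregated over 60-frame
   sliding windows (30-frame overlap) with (mean, std, max, min):
   68 variables + an organ indicator per (organ, window) record.
3. **Modeling** — one XGBoost classifier per target (six pathologies +
   "any prolapse"), positive records weighted by `|Neg|/|Pos|`,
   hyperparameters picked by randomized search scored by record-level
   average precision under grouped 5-fold cross-validation (no patient's
   records straddle folds). Patient diagnosis = majority vote over the
   patient's record calls (ties positive).
4. **Evaluation** — patient-level accuracy, precision, recall, F1 and
   expert-agreement fraction with 95% Wald confidence intervals.

See `docs/methods.md` for the model details, simulator assumptions and
numerical conventions.

## Worked example

Run the bundled 40-patient demo (simulate → features → train → evaluate,
about a minute on one CPU):

```bash
popsono run --config examples/demo.yaml --out demo_run
cat demo_run/report.csv
```

which prints (abridged; rectocele and enterocele are skipped in this small
cohort because no positive training patient was sampled):

```
target,agreement_pct,agreement_k,agreement_n,ci_low,ci_high,precision_pct,accuracy_pct,recall_pct,f1_pct
cystocele,84.6,11,13,65.0,100.0,60.0,84.615...,100.0,75.0
cystourethrocele,92.3,12,13,77.8,100.0,,92.307...,0.0,
uterine_prolapse,84.6,11,13,65.0,100.0,60.0,84.615...,100.0,75.0
cervical_elongation,92.3,12,13,77.8,100.0,50.0,92.307...,100.0,66.666...
any_prolapse,100.0,13,13,100.0,100.0,100.0,100.0,100.0,100.0
```

Reading the `any_prolapse` row: on the 13 held-out patients every
patient-level vote agreed with the simulated ground truth (agreement 13/13
= 100%, Wald CI degenerate at [100, 100]); for `cystocele` the model found
all true cases (recall 100%) but over-called two patients with other
prolapse types (precision 60%), the characteristic behaviour of the
all-organ vote discussed in the methods note. Empty cells are undefined
metrics (no positive cystourethrocele call was made, so precision and F1
are "-"). The run directory also contains the cohort label table with
measured descents in mm, the 69-column feature table (+ provenance
columns), one model bundle per trained target, patient-level predictions,
the resolved configuration with its hash and master seed, and a JSON-lines
log.

The stage-by-stage CLI (`popsono simulate / features / train / predict /
evaluate`) exposes the same pipeline for external data that follows the
HDF5/CSV interface, e.g.

```bash
popsono simulate --n-patients 20 --seed 3 --out cohort/
popsono features --in cohort/ --out features.csv
popsono train --features features.csv --target cystocele --seed 3 --out model/
```

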