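# Demo pipeline: 40 synthetic patients, all seven targets.
n_patients: 40
scene:
  n_frames: [100, 200]
targets:
  - cystocele
  - cystourethrocele
  - uterine_prolapse
  - cervical_elongation
  - rectocele
  - enterocele
  - any_prolapse
n_iter: 4
seed: 7
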