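# biokin

Landmark-based segmental spine kinematics: biokinemetric-triangle motion
curves, dS/S_max signatures, and presurgical implant planning.

## Who this is for

Surgeons and biomechanics researchers who work with *functional* spinal
imaging — calibrated sagittal X-rays or videofluoroscopy of the cervical
(C2–C7) or lumbar (L1–S1) spine in inclination, neutral position and
reclination — and want a quantitative, reproducible description of how each
motion segment moves, which segment is pathologically altered, what implant
height would restore it, and how an implant would redistribute motion to
the adjacent levels.

## The model

Each motion segment is reduced to a **biokinemetric triangle**: baseline on
the lower vertebra's upper endplate from the anterior edge (point 1) to the
ascending facet (point 2), apex at the posterior edge of the upper vertebra
at the neuroforamen roof (point 3).  With the baseline fixed by rigid
registration, segmental motion changes only the triangle's height, so its
area `S` (shoelace formula, millimetres after ball calibration) is the
motion measure.  From `S`:

* **RoM curve** — `S` versus the percentage of the section's global
  inclination→reclination sweep; sparse 3-pose exams are densified with a
  monotone cubic (PCHIP) interpolant.
* **Segment signature** — `dS / S_max = (S_max − S_min) / S_max`, a
  scale-invariant number per segment; a spine section is its
  cranial→caudal series.  Reproducibility of repeated exams is quantified
  as the Monte-Carlo **Bayes error** of a per-subject Gaussian
  identification problem (plus a 1-NN check) — low error means signatures
  behave like fingerprints.
* **Worst / best segment** — largest / smallest deviation from a stored
  healthy reference surrogate (best also requires preserved disc height).
* **Implant plan** — the best segment's geometry is virtually substituted
  into the worst; the recommended height is the donor height scaled by the
  level size-ratio quotient, capped at the reference neutral height
  (anti-overcorrection), then mapped to the device height grid.
* **Post-op prediction and dRoM** — the implanted level keeps
  `mobility_factor ×` its healthy range (0 for a rigid cage); the removed
  range is redistributed to the immediate neighbours proportionally to
  their current ranges, conserving the section total.  `dRoM` (the absolute
  change of a level's area range between exams) is the adjacent-segment
  effect measure and is correlated with outcome relief via a seeded
  permutation test.

Details, assumptions and limitations: [docs/methods.md](docs/methods.md).

## Worked example

No patient data ships with the package; the `synthetic_spine` generator
emulates calibrated landmark tables with known ground truth.  Simulate a
small implant cohort, analyze one pre-op exam, and plan its surgery:

```sh
$ biokin simulate --n-subjects 3 --noise 0.02 --seed 11 --out demo/cohort
cohort written to demo/cohort

$ biokin analyze --landmarks demo/cohort/landmarks_S001_pre.csv \
    --calibration demo/cohort/calibration.json \
    --reference demo/cohort/reference.json --out demo/analysis
worst level: C5-C6  best level: C4-C5
```

The report (`demo/analysis/report.json`) carries the signature series and
estimated disc heights:

```
signature ratios: C2-C3 0.438, C3-C4 0.419, C4-C5 0.343, C5-C6 0.559, C6-C7 0.402
disc heights mm:  C2-C3 6.14, C3-C4 6.43, C4-C5 6.77, C5-C6 4.83, C6-C7 6.64
```

The simulated patient's C5-C6 is unstable — its ratio (0.559) sits far from
the healthy ~0.44 and its disc has collapsed to 4.8 mm — so it is flagged
worst, while well-preserved C4-C5 is the donor.  Planning a cage for it:

```sh
$ biokin recommend --landmarks demo/cohort/landmarks_S001_pre.csv \
    --calibration demo/cohort/calibration.json \
    --reference demo/cohort/reference.json \
    --device demo/device.json --out demo/plan
target C5-C6: recommended 6.00 mm -> device height 6.0 mm (exact)
```

The recommendation restores the reference neutral height of C5-C6
(6.0 mm — the donor height scaled by the C5-C6/C4-C5 size ratio hits the
anti-overcorrection cap), and the plan's virtual post-op curves predict the
adjacent-level burden of the rigid cage (`adjacent dRoM`: C4-C5
18.7 mm², C6-C7 25.3 mm² of redistributed range).

The same workflows are available as library functions
(`biokin.workflows.analyze_exam`, `recommend_plan`,
`reproducibility_study`, `compare_exams`) on in-memory landmark tables.

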