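# exerscore

Objective scoring of rehabilitation-exercise performances from skeleton
recordings.

Patients practicing physiotherapy exercises at home get no feedback on how
well they are doing.  `exerscore` compares a recorded performance against a
reference performance (e.g. a physiotherapist's) and reports two 0–100%
similarity scores, for physiotherapists tracking progress remotely and for
developers of motion-sensing exercise applications.

## Method in brief

A performance is a session of 25-joint 3D skeleton frames (Kinect-V2-style
vocabulary, 30 fps).  Because raw positions depend on body size and camera
placement, each exercise is described by invariant joint angles per frame —
a trajectory **T** of shape *frames × d* in degrees (*d* = 3 for the lunge,
2 for shoulder abduction, hip abduction, and sit-to-stand).  Sessions
contain ≥ 5 repetitions; the middle 3 are scored.

Both scores are anchored by the *worst performance* **T_W** — not moving,
i.e. holding the rest pose:

* **DTW score.**  With *D* = DTW(T_R, T_P) the multivariate dynamic
  time-warping distance between reference and participant repetitions, and
  *D_u* = DTW(T_R, T_W) the worst-performance bound,

  &nbsp;&nbsp;&nbsp;&nbsp;S_D = 100 × (1 − D / D_u)

  averaged over all 3 × 3 repetition pairs (9 values).

* **HMM score.**  Angles are quantized to a small symbol alphabet and a
  discrete hidden Markov model λ_R is trained on the reference
  (Baum-Welch).  With L = log P(T_P | λ_R) / l the length-normalized
  forward log-likelihood, L_u = 0 and L_l the likelihood of the quantized
  worst trajectory,

  &nbsp;&nbsp;&nbsp;&nbsp;S_H = 100 × (L − L_l) / (0 − L_l)

  averaged over the 3 repetitions.

Multiplying D_u and |L_l| by a sensitivity factor smooths (> 1) or
sharpens (< 1) the scores.  See `docs/methods.md` for the full account,
including why the quantizer isolates the rest pose.

## Worked example

No hardware is needed: the package ships a session generator that emulates
the recording protocol (5 × 2 s repetitions, 1.5 s pauses, 30 fps,
sensor-jitter noise).  Score a full-range performer and a half-range
performer against a simulated reference:

```sh
exerscore simulate --exercise shoulder_abduction --side left --seed 1 \
    --features-only --out ref.csv
exerscore simulate --exercise shoulder_abduction --side left --seed 2 \
    --features-only --out good.csv
echo "rom_scale: 0.5" > half.yml
exerscore simulate --exercise shoulder_abduction --side left --seed 3 \
    --params half.yml --features-only --out weak.csv

for f in ref good weak; do
  exerscore segment --features $f.csv --exercise shoulder_abduction \
      --side left --select-middle --out $f.json
done

exerscore score-dtw --participant good.json --reference ref.json \
    --exercise shoulder_abduction --side left
exerscore score-hmm --participant good.json --reference ref.json \
    --exercise shoulder_abduction --side left --seed 7
exerscore score-dtw --participant weak.json --reference ref.json \
    --exercise shoulder_abduction --side left
```

prints

```
S_D = 94.8%
S_H = 97.3%
S_D = 66.4%
```

The full-range performer scores high on both measures; halving the range
of motion costs ~28 points of S_D.  (S_H stays high for this participant —
every symbol it emits is one the reference also visits — illustrating that
the HMM score captures the coarse shape of a movement and is less
sensitive to detail than DTW.)

From Python, the graded-cohort protocol makes the contrast explicit
(3 simulated participants per range-of-motion scale, mean scores):

```python
>>> from exerscore.experiments import rom_cohort_scores
>>> for s, row in rom_cohort_scores(seed=1).items():
...     print(f"rom {s:3.1f}:  S_D = {row['s_d']:5.1f}   S_H = {row['s_h']:5.1f}")
rom 1.0:  S_D =  91.4   S_H =  76.4
rom 0.8:  S_D =  84.7   S_H =  73.9
rom 0.6:  S_D =  70.4   S_H =  70.5
rom 0.4:  S_D =  50.2   S_H =  64.0
rom 0.2:  S_D =  24.1   S_H =  48.7
```

Both scores fall monotonically as range of motion shrinks, with DTW
reacting far more sharply — the full-ROM performer does not reach 100%
because of natural variability among repetitions, and a motionless
participant scores ≈ 0 on both.

`exerscore assess --config cohort.yml --out report.json` runs whole
cohorts (many participants × exercises) and writes JSON/CSV reports with
per-pair raw values, standard errors, the S_H − S_D difference, and
across-exercise averages; `examples/quantization_sensitivity.py` shows how
the cluster grid shifts HMM scores on identical data.

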