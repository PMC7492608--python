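# betarebound

Analysis pipeline for studying the **post-movement beta rebound (PMBR)** —
the transient increase in 13–30 Hz sensorimotor EEG power after a voluntary
movement ends — during *real-world* motor skill learning, modeled on a
pool-billiards paradigm: subjects repeat 300 self-paced shots (6 sets of 50,
analyzed as 12 blocks of 25) while single-channel EEG over the left motor
cortex, overhead ball tracking, full-body kinematics and head acceleration
are recorded.

The scientific question the pipeline serves: does the PMBR increase or
decrease as skill is acquired, and does that dynamic split learners into
mechanistically different groups?  PMBR rises over learning in error-based
adaptation tasks (tracking the decaying errors with a *negative*
PMBR–error correlation) but falls in reward-based skill tasks (*positive*
correlation).  The pipeline computes, per subject, the Pearson correlation
over blocks between the block-averaged PMBR and the block mean absolute
directional error, then asks — with Gaussian mixtures selected by AIC/AICc
and, independently, fuzzy c-means selected by a validity index — whether
the cohort is bimodal: **PMBR Increasers** (r < 0, putative error-based
learners) vs **PMBR Decreasers** (r > 0, putative reward-based learners).

Because the original recordings are not publicly deposited, the package
includes a first-class synthetic-cohort generator calibrated to the study's
reported structure (group sizes 16/14, coupling distributions −0.40 ± 0.26
and +0.47 ± 0.17, learning rates 0.48/0.60, group contrasts in variability
decay, trial-to-trial change, ACF(1) decay and movement complexity), so
every stage is validated by parameter recovery.

## What is in the box

| module | what it does |
| --- | --- |
| `betarebound.synth` | cohort generator: AR(1) error series with decaying bias/SD, EEG with calibrated beta bursts, ball tracks, kinematics with targeted complexity, head acceleration; EDF/CSV output |
| `betarebound.tracking` | cue-ball onset from a 40×40 mm bounding box, signed directional error at peak target speed, trial/set/block segmentation |
| `betarebound.spectral` | 5–35 Hz FIR filtering, Morlet time–frequency maps (1 Hz steps, 7 cycles), log/block-average % normalization, per-trial PMBR and baseline beta |
| `betarebound.behavior` | learning curve and rate, intertrial variability and decay, trial-to-trial change, ACF(1) over session halves, manipulative complexity, head-movement summaries |
| `betarebound.grouping` / `betarebound.fuzzy` | PMBR–error correlations, GMM selection by AIC/AICc, fuzzy c-means + validity index, group labels, trend fits, control correlations |
| `betarebound.pipeline` | in-memory and disk-based orchestration, manifests/caching, report tables and figures |
| `betarebound.cli` | `betarebound simulate / analyze / report / all` |

## Worked example

```python
import numpy as np
from betarebound import CohortConfig, RunConfig, analyze_cohort, generate_cohort

cohort = generate_cohort(CohortConfig(n_subjects=5, n_negative_coupling=3, seed=21))
res = analyze_cohort(cohort, RunConfig(seed=21))
for row, s in zip(res["subjects"].itertuples(), cohort.subjects):
    print(f"{row.subject}  fitted r = {row.pmbr_error_r:+.3f}  "
          f"(programmed {s.true_corr:+.3f})  LR = {row.learning_rate:.2f}")
```

prints (seed 21):

```
sub-01  fitted r = +0.438  (programmed -0.205)  LR = 0.61
sub-02  fitted r = -0.774  (programmed -0.510)  LR = 0.52
sub-03  fitted r = -0.535  (programmed -0.460)  LR = 0.49
sub-04  fitted r = +0.461  (programmed +0.612)  LR = 0.66
sub-05  fitted r = +0.667  (programmed +0.639)  LR = 0.51
```

Each line is one synthetic subject: the pipeline extracted per-trial PMBR
values from the raw synthetic EEG, recovered the directional errors from
the ball tracks, and correlated the two over the 12 learning blocks.  Most
fitted correlations land near the programmed coupling; sub-01 shows the
flip side — with only 12 blocks a weakly coupled subject (true r = −0.21)
can come out with the opposite sign.  That sampling scatter is intrinsic
to the design and is exactly why the grouping analysis is run at the
cohort level, where the bimodal structure is recovered reliably.

The scripts in `examples/` each demonstrate one capability (cohort
simulation, PMBR extraction, tracking geometry, behavioral metrics,
bimodal grouping) and print a short interpretation of their output.

The shell pipeline produces the same results from files on disk:

```bash
betarebound all --seed 1 --out results/
```

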