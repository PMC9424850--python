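# tapfatigue

Analysis chain for repetitive four-target tapping sessions: shoulder-muscle
fatigue from surface EMG, movement variability and local dynamic stability
from body-worn accelerometers, and end-point task performance from
touch-screen tap logs — together with a synthetic-data generator that plants
a known value for every index the chain computes, so the whole pipeline is
verifiable by parameter recovery.

## The problem

Prolonged repetitive fine-manipulation work (think laparoscopic suturing at a
worktable) fatigues the shoulder. A session here is 400 tapping cycles over
four touch screens (TS1→TS2→TS3→TS4, counterclockwise), performed at two
worktable heights — elbow height (LOW) and 120% of it (HIGH) — while
recording:

* 3-channel surface EMG of the anterior/medial/posterior deltoid (1926 Hz),
  with a maximum-voluntary-contraction (MVC) reference trial;
* 3-axis gravity-removed acceleration of the lower arm, upper arm and trunk
  (9 channels);
* a tap log (screen id, timestamp, pixel coordinates).

The 400 cycles are grouped into 10 bins of 40 cycles; every index below is
reported per bin per height.

## Indices

* **Muscle activity / fatigue** — moving RMS in 0.125 s windows (50%
  overlap) as %MVC, and the median frequency MF: the frequency splitting each
  window's power spectrum into equal halves. MF drifts downward as fatigue
  accumulates.
* **Cocontraction** — CCI = 100 · ∫min(EMG_ago, EMG_ant) dt / ∫(EMG_ago +
  EMG_ant) dt over the anterior (agonist) and posterior (antagonist) deltoid
  %MVC envelopes, per stage ST1..ST4 and per full cycle; bounded by 50 for
  equal envelopes.
* **Kinematic variability** — cycles resampled to 100 phase points; KV =
  mean over phase of the between-cycle SD, per axis; per sensor the Euclidean
  norm of its three axes (KV_LA, KV_UA, KV_TR).
* **Local dynamic stability** — the nine channels are projected onto their
  three dominant principal components; Rosenstein-style nearest-neighbor
  divergence y(k) gives the largest Lyapunov exponent λ as the slope of y(k)
  over 5%, 10%, quarter- and half-cycle horizons (λ5, λ10, λQ, λH).
* **Task performance** — accuracy score AS = 100 · (r − d)/r for a tap at
  distance d from the center of the r = 8.415 mm target circle; tapping
  deviation TD = mean distance of a bin's taps from their own centroid
  (precision); task time = TS1-to-TS1 cycle duration.
* **Inference** — first-bin ratio normalization, paired HIGH-vs-LOW t-tests
  over participant × bin pairs, and per-height repeated-measures ANOVAs over
  five 2-bin periods gating Bonferroni-corrected follow-ups (p < 0.0125).

## Worked example

```sh
tapfatigue simulate --out session/ --seed 7      # two-height synthetic session
tapfatigue analyze session/                      # per-bin index tables
tapfatigue report session/results                # normalized group statistics
```

or, the same flow as numbered scripts with narrative output:

```sh
python analysis/01_simulate_session.py
python analysis/02_analyze_session.py
python analysis/03_validate_recovery.py
python analysis/04_group_inference.py
```

The simulated HIGH condition plants faster fatigue and looser end-point
control than LOW; the analysis recovers exactly that (seed 7):

```
MF_ANT   LOW  bin1=  81.287  bin10=  78.109
MF_ANT   HIGH bin1=  79.972  bin10=  71.385
RMS_ANT  LOW  bin1=   9.779  bin10=   9.777
RMS_ANT  HIGH bin1=  13.777  bin10=  13.757
AS_TS3   LOW  bin1=  79.478  bin10=  82.108
AS_TS3   HIGH bin1=  75.661  bin10=  73.096
TD_TS3   LOW  bin1=   1.713  bin10=   1.504
TD_TS3   HIGH bin1=   2.026  bin10=   2.254
TIME     LOW  bin1=   2.190  bin10=   2.010
TIME     HIGH bin1=   2.045  bin10=   1.955
```

MF declines faster at HIGH (fatigue), RMS is ~4 %MVC higher (effort), the
accuracy score is lower, tapping deviation higher, and cycles slightly
faster. Parameter recovery on dedicated 400-cycle designs
(`analysis/03_validate_recovery.py`):

```
                 quantity  planted  recovered  err_pct
       lambda5 (1/sample)   0.0500     0.0509   1.7634
      KV per axis (m/s^2)   0.2000     0.1968   1.5879
                  TD (mm)   1.5040     1.5307   1.7792
```

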