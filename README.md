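# tacitload

EEG theta/beta-ratio analysis of cognitive load in **tacit coordination
games** — a tested, reusable pipeline for researchers who want to relate an
electrophysiological load index to behavioural coordination ability.

In a tacit coordination game two players are rewarded for choosing the same
option (here: one of four words) without communicating; some options act as
*focal points* that attract convergent choices. The package links three
levels of observation collected in a single session — resting state, a
"picking" block (free choice), and a "coordination" block (choose what your
unseen partner chooses):

* **TBR (theta/beta ratio)** — per 1-s epoch and electrode,
  `TBR = E_θ / E_β`, where band energies come from a 3-level Daubechies-4
  discrete wavelet transform of the 64 Hz signal (detail 1 → β 16–32 Hz,
  detail 2 → α 8–16 Hz, detail 3 → θ 4–8 Hz, approximation → δ 0–4 Hz).
  Lower TBR indicates higher cognitive load.
* **CI (coordination index)** — per game, the probability that two distinct
  players drawn without replacement chose the same label,
  `CI = Σ_l n_l(n_l−1) / (N(N−1))`; a measure of how easy the game is.
* **iCA (individual coordination ability)** — per player, the normalised
  pairwise agreement with the rest of the population,
  `iCA_i = Σ_g m_i(g) / (G(N−1))`.

The inferential stage runs a pooled one-way ANOVA with Tukey HSD post-hoc
over the three conditions (six frontal/prefrontal electrodes: Fp1, F7, Fp2,
F8, F3, F4), a RANSAC-robust first-order regression of per-game mean TBR
(channel F4) on CI, a linear fit of per-subject TBR on iCA, and a quadratic
fit of response time on per-trial TBR.

Because raw human recordings from such studies are rarely shareable, the
package ships a first-class synthetic-data generator: 16-channel 10–20
recordings at 512 Hz with condition-dependent theta/beta oscillations, 1/f
background noise, 50 Hz line noise and eye blinks, plus a matched
behavioural choice model in which a single latent "depth of reasoning" per
subject drives both choice sharpening and cognitive load. Every analysis
stage is therefore testable end to end, with known planted effects. Real
data can be ingested from channel-major delimited text or EDF (optional
`mne` extra).

## Worked example

```bash
tacitload --seed 0 run-all --out-dir demo_out
cat demo_out/report.txt
```

or equivalently from Python:

```python
from tacitload import GeneratorConfig
from tacitload.pipeline import PipelineConfig, run_all

run_all(PipelineConfig(generator=GeneratorConfig(seed=0)), "demo_out")
```

which prints (abridged):

```
TBR distribution by condition (frontal electrodes):
   condition    n  n_dropped  median    q25    q50    q75
coordination  720          0  2.6579 1.3336 2.6579 4.7582
     picking  720          0  3.8627 2.4442 3.8627 5.4696
        rest 3600          0  4.5770 3.0898 4.5770 6.7371

One-way ANOVA over conditions: F(2,5037) = 109.5, p = 2.845e-47
...
RANSAC inliers: 12/12 games = 100% of the data
TBR-on-CI (inliers): Y = 0.3266 + 5.4406·X
  R2_inliers = 0.5981, F = 14.88, p = 0.003171, VAR_error = 0.932
TBR-on-iCA: TBR = 6.8899 - 5.8827·iCA (R2 = 0.4127)
RT-on-TBR (quadratic): RT = 2.0730 - 0.1512·TBR + 0.0097·TBR^2 (p = 0.0001003)
```

Reading the output: median TBR falls from rest (4.58) through picking
(3.86) to coordination (2.66) — load rises as the task demands deeper
reasoning, and all pairwise condition differences are significant. Easier
games (higher CI) show higher mean TBR (positive slope, computed on the
RANSAC consensus set), better coordinators (higher iCA) show lower TBR, and
trials with lower TBR take longer — the planted qualitative pattern the
generator encodes.

The run directory also contains every intermediate table (`bandpower.csv`,
`ci.csv`, `ica.csv`, `anova.csv`, `tukey.csv`, `regression_*.csv`), a
scatter figure of CI vs TBR with flagged outliers, and `manifest.json`
recording the config hash, seed and row counts of every output.

Stage-wise execution (`simulate`, `preprocess`, `extract-tbr`, `metrics`,
`stats`, `report`) is available for working with on-disk intermediates; a
flat `key = value` config file (`--config`) fully determines a run.

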