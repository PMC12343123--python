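# skatesurv

Post-release survival inference for deep-sea skates from pop-up satellite
archival tag (PSAT) summaries.

Deep-sea skates (*Bathyraja* spp.) are frequent bycatch on demersal
longlines set at 1200–1600 m for Patagonian toothfish. Skates landed in
good condition are released, but whether they survive the haul from those
depths is cryptic: the only evidence comes back through miniPAT tags that
record depth, temperature and acceleration at 1 Hz, then detach, surface
and transmit lossy summaries — depth at 150 s cadence quantized to 16 bins
per 2 h window (sensor accuracy ±1% of reading), the per-window mean of a
unit-less "tag mobility" metric (range 5–63), and the fraction of each
window the tag floated upright (vertical acceleration A_z ≤ −0.75 g).

This package implements the full inference chain from those summaries to a
survival rate, plus a seeded synthetic-deployment generator for validating
every step against known ground truth:

- **Sensor/observation model** (`skatesurv.tag_model`) — accuracy band
  `±0.01·depth`, 16-step window binning with bin-centre decoding,
  summarization of recovered 1 Hz archives, CSV I/O.
- **Synthetic deployments** (`skatesurv.synthetic_tags`) — latent 1 Hz
  behaviour → sensor model → 20% transmission dropout, for five regimes:
  active survivor, dead on the plateau, dead under tidal current forcing in
  a canyon, an ambiguous sluggish animal, and a dead control.
- **Activity metrics** (`skatesurv.activity`) — stillness (mobility < 9),
  still bouts (> 24 h), tilt hours, Lomb–Scargle periodicity screening with
  a permutation significance test.
- **Mobility HMM** (`skatesurv.mobility_hmm`) — a pooled two-state Gaussian
  hidden Markov model (states "non-mobile"/"mobile") fitted by Baum–Welch,
  with per-tag Viterbi decoding.
- **Fate calls** (`skatesurv.fate`) — vertical movement judged against the
  sensor error band at the benthic median (±13–18 m at 1300–1800 m), a
  Bray–Curtis NMDS diagnostic of the activity summaries, and an ordered
  rule table: movement → survivor; no movement ∧ non-mobile → mortality; no
  movement ∧ mobile → ambiguous.
- **Survival estimation** (`skatesurv.survival`) — binomial proportion with
  the 95% Wilson score interval

  `(p̂ + z²/2n ± z√(p̂(1−p̂)/n + z²/4n²)) / (1 + z²/n)`,

  a CI-width/sample-size planning curve, and a binomial GLM (logit link) of
  survival on capture depth, length, sex, time out of water and soak time,
  reported as an odds ratio per 100 m shallower.

## Worked example

```sh
python analysis/01_simulate.py --seed 7          # 24-tag cohort + truth
python analysis/02_activity_summaries.py --seed 7
python analysis/03_classify_fates.py --seed 7
python analysis/04_survival_estimate.py --seed 7
python analysis/05_depth_effect.py --seed 7
```

`03_classify_fates.py` prints, for the default seed-7 cohort:

```
pooled HMM: non-mobile mean 8.0 (sd 0.5), mobile mean 25.5 (sd 10.8), 12 EM iterations
HMM split: 8 mobile / 16 non-mobile
NMDS stress-1: 0.0001

fate calls vs truth (accuracy 100%):
fate_called  ambiguous  mortality  survivor
fate_true
ambiguous            2          0         0
mortality            0         16         0
survivor             0          0         6
```

i.e. the HMM separates the two latent activity levels, the six tags with
vertical movements beyond the sensor error band are called survivors, the
two sluggish tags land in the ambiguous class, and `04_survival_estimate.py`
then reports `6/23 = 26% (95% Wilson CI 13–46%)` with the ambiguous tags
counted as mortalities and the control excluded, and a planning curve
showing about 101 tags would be needed to halve the interval width.  At
n = 23 the depth GLM quasi-separates (survivors were caught shallower than
every mortality) and the pipeline says so rather than reporting an
unbounded odds ratio; `05_depth_effect.py` fits the same model at n = 200
with a designed odds ratio of 5 per 100 m shallower and prints
`fitted OR per 100 m shallower: 6.57 (95% CI 3.96–10.90)`.

The same pipeline is scriptable end to end:

```sh
skatesurv all --seed 7 --outdir results/cohort
```

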