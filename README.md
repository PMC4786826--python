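# spineshm

Vibration-based structural health monitoring (SHM) of the lumbar spine, as a
tested, reusable analysis pipeline.

SHM assesses a structure's integrity from its response to applied vibration.
Applied non-invasively to the spine, the protocol is: a shaker drives the
spinous process of T12 with a train of 10 one-second pulses of randomized
frequencies (1–2000 Hz, sampled at 5000 Hz, 5 N contact preload), while five
skin-mounted accelerometers over L1–L5 record the response; three pulse
trains are collected per subject.  In a monozygotic-twin design, pairs whose
lumbar spines are structurally concordant on MRI should produce statistically
indistinguishable responses, while structurally discordant pairs (one twin
with, e.g., a compression fracture) should differ.

`spineshm` provides:

* **`spine_sim`** — a lumped-parameter stand-in for the in-vivo system: a
  six-node mass–spring–damper chain (T12, L1…L5) grounded at T12, driven by
  a flat-magnitude random-phase multisine pulse train, with distance-dependent
  soft-tissue attenuation, white sensor noise, twin biological variability,
  and localized structural alterations; plus a seeded twin-cohort generator.
* **`spectral_estimation`** — pulse-averaged auto-/cross-spectra; the
  frequency response function FRF(f) = P_aa(f)/P_ff(f) (output power over
  input power); magnitude-squared coherence
  γ²(f) = |P_fa(f)|² / (P_ff(f)·P_aa(f)); running-median FRF smoothing.
* **`frf_outcomes`** — per-sensor scalar outcomes from the smoothed FRF:
  PEAK (frequency of the FRF maximum), AUC (trapezoidal integral over the
  band) and RMS (root mean square across bins); coherence-based sensor QC;
  averaging over a subject's three trials.
* **`twin_comparison`** — within-pair signed differences per sensor and
  outcome, one-sample (paired) t-tests and ANCOVA of the mean difference
  against zero, and a group × outcome × sensor report; plus the transcribed
  study metadata (20 subjects, 10 twin pairs) and recruitment counts.
* **`io` / `cli`** — CSV/YAML readers and writers and a `spineshm` command
  with `simulate`, `analyze`, `compare` and `cohort` subcommands.

## Worked example

```python
import spineshm as sh

# simulate a cohort of 5 concordant and 5 discordant twin pairs; in each
# discordant pair one twin has the T12-L1 link stiffness halved
cohort = sh.generate_twin_cohort(5, 5, seed=42)
report = sh.analyze_cohort(cohort)          # full pipeline + paired t-tests
peak = report[(report.group == "Discordant") & (report.outcome == "PEAK")]
print(peak[["sensor", "mean_difference", "p_value", "significant"]].to_string(index=False))
```

```
sensor  mean_difference  p_value  significant
    L1         8.266667 0.000037         True
    L2         8.133333 0.000019         True
    L3         8.200000 0.000026         True
    L4         8.083333 0.000299         True
```

The altered twin's softened link lowers the chain's fundamental resonance by
roughly 8–10 Hz, so the within-pair PEAK difference is positive and nearly
identical at every retained sensor and the paired t-test rejects the zero-mean null
(p < 0.05) — while for concordant pairs, and for all outcomes in concordant
pairs, differences stay at noise level.  The most distal sensor (L5) is
excluded automatically: its mean coherence (≈0.1 with the default
attenuation and noise floor, against ≈0.69–0.88 for L1–L4) falls below the
0.5 QC threshold, so group tests cover L1–L4.

The same analysis runs from the shell:

```bash
spineshm simulate --pairs-concordant 5 --pairs-discordant 5 --seed 42 --out cohort/
spineshm cohort --manifest cohort/manifest.csv --out report.csv
```

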