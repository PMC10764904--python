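# chronofp

Patient-specific EEG seizure prediction with **chronology-aware firing-power
post-processing**.

Seizure prediction algorithms try to raise an alarm during a *preictal*
period before a seizure onset, early enough (the Seizure Prediction Horizon,
SPH) for the patient to act, and within a bounded window (the Seizure
Occurrence Period, SOP) so the warning is meaningful. `chronofp` implements a
complete patient-specific pipeline built on the idea — motivated by the
epileptic-network view of seizure generation — that the preictal period is
not a single homogeneous state but a *chronological cascade of brain-activity
events*, and that this chronology can be exploited in the post-processing
stage rather than in the classifier itself.

## What the package does

1. **Synthetic patients** (`chronofp.synthetic`) — annotated 19-channel,
   256 Hz scalp-EEG-like recordings: colored-noise background plus up to
   three chronologically ordered preictal stages with configurable
   band-power signatures and effect size. Null patients (`effect_size=0`)
   carry no signal at all.
2. **Features** (`chronofp.features`) — non-overlapping 5-s windows; per
   channel, 59 univariate linear features: band powers (absolute, relative,
   24 ratios), spectral edge / peak / mean frequency, statistical moments,
   Hjorth parameters, decorrelation time, and Daubechies-4 wavelet energies.
3. **Dataset** (`chronofp.dataset`) — preictal/interictal labeling under a
   Control (one event of length SOP), Chronological (three consecutive
   events of length SOP) or Cumulative (three nested events of lengths SOP,
   2·SOP, 3·SOP) scheme; per-seizure systematic random undersampling;
   z-score normalization; ANOVA-F feature selection.
4. **Model** (`chronofp.model`) — 31 linear-kernel SVMs, one per
   undersampling draw, combined by majority vote; hyperparameters (k ∈
   {10,20,30,40} features, C ∈ {2⁻¹⁰…2¹⁰}, SOP ∈ {10…55} min) tuned by
   leave-one-seizure-out cross-validation with the √(SS·SP) metric.
5. **Post-processing** (`chronofp.postproc`) — the firing power
   fp[n] = Σₖ₌ₙ₋τⁿ O[k]/τ smooths the binary vote stream; alarms by three
   strategies: threshold crossing (Control), ordered triple of event
   occurrences (Chronological), or a summed curve crossing 0.5/1.0/1.5
   sequentially (Cumulative); refractory period SOP+SPH.
6. **Evaluation** (`chronofp.evaluation`) — seizure sensitivity
   SS = predicted/all seizures; FPR/h = false alarms / (interictal duration −
   false alarms × refractory); seizure-time surrogate test (onsets relocated
   uniformly into the interictal period, alarms held fixed, one-sided rank
   p-value at α = 0.05).
7. **Pipeline & CLI** (`chronofp.pipeline`, `chronofp.cli`) — per-patient,
   per-approach orchestration with a single master seed, plus the
   `chronofp` command (`simulate`, `features`, `dataset`, `train`,
   `predict`, `postproc`, `evaluate`, `run-all`).

## Worked example

```python
from chronofp import RunConfig, run_patient
from chronofp.model import GridSpec
from chronofp.synthetic import SyntheticConfig

cfg = RunConfig(
    synthetic=SyntheticConfig(n_channels=4, n_seizures=5,
                              interictal_gap_min=80.0, seed=11),
    grid=GridSpec(k_grid=(10, 20), c_grid=(0.25, 1.0, 4.0), sop_grid=(10, 15)),
    seed=11,
)
for approach, res in run_patient(cfg).items():
    print(f"{approach:14s} SOP={res['sop']:2d}  SS={res['ss']:.2f}  "
          f"FPR/h={res['fpr_h']:.2f}  p={res['p_value']:.3f}  "
          f"validated={res['validated']}")
```

which prints (default three-stage theta/alpha/beta cascade, effect size 1):

```
control        SOP=10  SS=1.00  FPR/h=0.00  p=0.032  validated=True
chronological  SOP=10  SS=1.00  FPR/h=0.00  p=0.032  validated=True
cumulative     SOP=10  SS=0.00  FPR/h=3.00  p=1.000  validated=False
```

Read: Control and Chronological predict both test seizures with no false
alarms and beat all 30 seizure-time surrogates (rank p = 1/31 ≈ 0.032 <
0.05 — above chance). The Cumulative run on this patient illustrates the
*all-or-nothing* character of alarm-based evaluation: its alarms fire at
304.6 and 384.2 min, less than a minute before the 10-min prediction
windows open at 305 and 385 min, so both count as false alarms and the
refractory period then silences the true window — sensitivity 0 even
though the curves track the cascade. Across 10 seeded replicates of this
condition (with fixed hyperparameters; see `chronofp.experiments`) the
Cumulative strategy predicts and validates 9–10 of 10 patients. On *null*
patients the same pipeline is validated only at the nominal false-positive
rate of the surrogate test — that calibration is exercised by the test
suite and the acceptance script.

The same run from the shell:

```bash
chronofp run-all --config run.yaml --out results/patient01/
```

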