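# perfusekit

Dynamic CT myocardial-perfusion analysis with a digital heart phantom.

Dynamic contrast-enhanced CT can grade myocardial ischaemia downstream of a
coronary stenosis, but conventional Hounsfield-unit (HU) image noise makes
voxel-wise kinetic fitting unreliable. Detector-based dual-energy ("spectral")
CT yields absolute iodine-density maps (mg/mL) with a clean 0 mg/mL baseline
and far higher contrast-to-noise, enabling voxel-wise perfusion
quantification. `perfusekit` provides the full analysis chain for this kind
of experiment, aimed at CT-physics and perfusion-imaging researchers:

- a **digital dynamic phantom** with three myocardium-like tissue bands
  (highly / moderately / not affected by a simulated stenosis), a blood-pool
  region carrying a gamma-variate contrast bolus, ECG-triggered sampling, and
  per-modality noise calibrated to blood-pool ROI SNR;
- **one-compartment tracer-kinetic fitting**: the tissue time-attenuation
  curve (TAC) is modelled as `TAC(t) = A · (AIF ⊛ e^{−λt})(t)`, with the
  inflow rate constant `A` (s⁻¹) and washout rate `λ` (s⁻¹) estimated
  voxel-wise by bound-constrained least squares (L-BFGS-B), with parameter
  errors `Δx_i = sqrt(f_stop · (H⁻¹)_ii)` from the optimiser's stopping
  bound and the inverse Hessian;
- **perfusion maps** via the central volume principle: MTT = 1/λ (s),
  volume fraction = 100·A/λ (mL/100 mL), blood flow = 6000·A
  (mL/min/100 mL), so that v = BF·MTT/60 identically;
- **ischaemia classification**: an MTT threshold classifier swept into a ROC
  curve (trapezoid AUC = Mann–Whitney concordance) with percentile-bootstrap
  confidence intervals;
- **dose arithmetic and temporal undersampling**: DLP = n·CTDIvol·coverage,
  effective dose = DLP·k, and a uniform keep-k-of-n frame subsetting that
  emulates a reduced-dose protocol.

The voxel-wise fitter (`OneCompartmentModel`) and the MTT band classifier
(`MTTBandClassifier`) are scikit-learn-style estimators and compose with
sklearn tooling; module-level functions (`fit_volume`, `classify_thresholds`,
…) are thin wrappers over them.

## Worked example

```python
import perfusekit as pk

phantom = pk.PhantomConfig()          # 36 time points over ~26.9 s,
                                      # region MTTs 2.73 / 2.2 / 1.8 s,
                                      # blood-pool ROI SNR 112.02 (spectral)
res = pk.run_classification_experiment(phantom, "iodine_density", seed=1)
print(f"blood-pool ROI SNR: {res['roi_snr']:.2f}")
print(res["mtt_stats"].to_string(index=False))
print(f"AUC {res['roc'].auc:.3f} "
      f"[{res['ci'].lower:.3f}-{res['ci'].upper:.3f}]")
```

prints

```
blood-pool ROI SNR: 110.75
    region     mean       sd   n
    highly 2.739249 0.136977 640
  moderate 2.200488 0.120938 640
unaffected 1.800671 0.103891 640
AUC 0.998 [0.997-0.999]
```

The measured blood-pool SNR reproduces the configured calibration (112.02),
and the per-region mean ± SD MTT of the fitted maps recovers the configured
plateaus (2.73 / 2.2 / 1.8 s) with a per-voxel scatter of ~0.1 s. The ROC
classifies hypoperfused (highly + moderately affected) against unaffected
voxels by thresholding MTT: at this noise level the separation is nearly —
but not exactly — perfect, because the per-voxel MTT scatter sits at the
Cramér–Rao limit of the 36-point acquisition (see `docs/methods.md`).

The same chain runs from the shell:

```bash
perfusekit simulate --modality spectral --seed 1 --out out/
perfusekit dose --n-timepoints 36 --ctdi 9 --coverage 4 --k 0.015 --reduced 8
perfusekit run --seed 1 --out out/   # full report: both modalities + reduced dose
```

`perfusekit dose` above prints the protocol arithmetic: DLP 1296 mGy·cm,
effective dose 19.44 mSv (≈19), reduced-protocol dose 4.32 mSv (4.3), a
77.8 % (≈78 %) reduction.

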