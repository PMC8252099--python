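# saturn-relaxometry

Simultaneous quantification of the three clinically used myocardial
relaxation times — T1, T2, and T2\* — from a single free-breathing scan is
the idea behind the SATURN family of sequences (**SA**turation and
**T**2-prepared **R**elaxometry with **N**avigator gating): a single-shot
multi-gradient-echo readout acquires 7 differently prepared contrasts
(1 unprepared, 2 T2-prepared, 4 saturation-prepared) at 5 echo times,
yielding 35 co-registered magnitude images in under half a minute.

This package is a desk-scale toolkit around that acquisition for sequence
developers and quantitative-MRI researchers:

* a **Bloch simulator** of the prepared multi-GRE sequence (WET saturation,
  composite 90°–MLEV–270° T2 preparation, spoiled centric readout, navigator
  gating and rest-period timing),
* the **joint 5-parameter fit**

  $$S(\mathrm{TS}, \mathrm{T2p}, \mathrm{TE}) = \Big[A\,\big(1 - e^{-\mathrm{TS}/T_1}\big)\,e^{-\mathrm{T2p}/T_2} + B\Big]\; e^{-\mathrm{TE}/T_2^*}$$

  with echo truncation against the Rician noise floor, plus the
  single-parameter reference fits (saturation-recovery T1, T2-prepared
  3-parameter T2, multi-echo T2\*),
* **digital phantoms** (tube grid, short-axis ring) with Rician noise and
  rigid motion corruption,
* **precision (SD) maps** from the fit Jacobian, rigid mutual-information
  registration, AHA 6-segment bullseye statistics, Bland–Altman comparison,
  and the **confounder simulation study** (rest period, noise, heart rate,
  T2-preparation efficiency).

No scanner data are required: everything runs on synthetic phantoms.

## Worked example

Simulate a myocardial voxel (T1 = 1573 ms, T2 = 33.2 ms, T2\* = 25.3 ms)
through the default protocol at 60 bpm and fit it back:

```python
import numpy as np
from saturn import (TissueParams, build_saturn_protocol,
                    simulate_acquisition, fit_saturn, compute_sd)
from saturn.phantom import add_rician_noise

protocol = build_saturn_protocol(heart_rate=60)   # 7 contrasts x 5 echoes
tissue = TissueParams(T1=1573, T2=33.2, T2star=25.3)
series = simulate_acquisition(protocol, tissue)   # 35 magnitude samples

fit = fit_saturn(series)
p = fit.params
print(f"fitted: T1 = {p.T1:.1f} ms, T2 = {p.T2:.2f} ms, T2* = {p.T2star:.2f} ms")

ref = series.magnitude[np.isinf(series.TS) & (series.T2p == 0)][0]
noisy = fit_saturn(add_rician_noise(series, 20, ref, seed=42), noise_sd=ref/20)
sd = compute_sd(noisy)
q = noisy.params
print(f"SNR 20: T1 = {q.T1:.0f} +/- {sd['T1']:.0f} ms, "
      f"T2 = {q.T2:.1f} +/- {sd['T2']:.1f} ms, "
      f"T2* = {q.T2star:.1f} +/- {sd['T2star']:.1f} ms")
```

prints

```
fitted: T1 = 1483.5 ms, T2 = 33.25 ms, T2* = 25.30 ms
SNR 20: T1 = 1639 +/- 174 ms, T2 = 30.5 +/- 2.4 ms, T2* = 21.7 +/- 3.8 ms
```

The noise-free fit recovers T2 and T2\* essentially exactly; T1 reads ~6 %
low because the clinical 4-second rest periods leave the longitudinal
magnetization slightly under-recovered (with 10 s rest the deviation drops
below 0.1 % — see `docs/methods.md`). At SNR 20 the second line shows the
voxel-wise precision estimate an SD map would contain: the Rician noise
floor biases T1 upward and T2\* is the most noise-sensitive parameter.

The same pipeline is scriptable from the shell:

```bash
saturn protocol --heart-rate 60 -o protocol.yaml
saturn simulate --t1 1573 --t2 33.2 --t2star 25.3 -o series.csv
saturn phantom --kind ring --snr 20 --seed 1 -o data/
saturn fit --stack data/stack.nii --noise-sd 0.016 -o maps/
saturn study --which noise --mc-size 1000 -o study/
saturn bullseye --snr 30 -o bullseye/
```

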