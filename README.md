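# mukin — wrist kinematics from motor unit discharge timings

Myoelectric prosthesis control traditionally maps time-domain features of
the interference EMG onto commands. `mukin` implements the alternative:
predict the joint angles of the three wrist degrees of freedom (DoFs) by
linear regression on **neural features** — motor-unit spike trains
obtained from high-density surface EMG decomposition — and compare them
against the classic time-domain (TD) feature set under a matched
cross-validation protocol.

The core of the package is a physiologically motivated **model-based
dimensionality reduction**. Motor neurons of a pool share a large part of
their synaptic input, so each unit's discharge pattern is a noisy view of
one common drive. For every unit *j* assigned to DoF *i*, a linear map
*g<sub>ij</sub>* from its windowed spike count *x<sub>ij</sub>* to the
joint angle is estimated by robust regression (Tukey bisquare IRLS),
giving a per-window input proxy *α<sub>ij</sub> = g<sub>ij</sub>(x<sub>ij</sub>)*.
The per-DoF activation is the recursive median

&nbsp;&nbsp;&nbsp;&nbsp;*a<sub>i</sub><sup>r</sup> = median(α<sub>i1</sub>, …, α<sub>in</sub>, a<sub>i</sub><sup>r−1</sup>)*,

robust to up to ⌊(n−1)/2⌋ grossly wrong unit estimates per window and
smooth over time through the recursion term. The three activations plus
TD features of the **residual EMG** (recording minus the spike-triggered-
average reconstruction) form the proposed feature set; AM1 (spike counts +
residual, PCA), AM2 (spike counts only, PCA) and TD are the baselines.

No recordings ship with the package. A built-in simulator generates
complete sessions — triangular single-DoF cues at three speeds,
recruitment-ordered motor-neuron pools driven by the kinematics,
multichannel MUAP mixing on an 8×8 grid with additive noise, and a
configurable decomposition-error model (missed spikes, false positives,
partial detection biased toward high-threshold units) — so the entire
pipeline is testable end to end with known ground truth.

## Worked example

```python
from mukin import SessionConfig, CorruptionSpec, simulate_session, run_comparison

config = SessionConfig(
    ramp_duration=1.0,          # fast ramps: 1 s per direction
    units_per_pool=16,
    corruption=CorruptionSpec(miss_rate=0.2, false_positive_rate=2.0,
                              detected_fraction=0.7, high_threshold_bias=1.0),
)
session = simulate_session(config, seed=42)
print(f"{session.spikes.n_units} decomposed units, "
      f"{session.emg.n_samples / session.emg.sample_rate:.0f} s of 64-channel EMG")

report = run_comparison(session, kinds=("TD", "AM2", "PROPOSED"), repeats=2, seed=0)
print(report.aggregate().to_string(index=False))
```

prints

```
68 decomposed units, 78 s of 64-channel EMG
    kind  ramp_duration_s  mean_r2    sd_r2  n_cells
     AM2              1.0 0.881644 0.042402       18
PROPOSED              1.0 0.918122 0.015551       18
      TD              1.0 0.951893 0.006844       18
```

Each row is a feature set's held-out performance under repeated 3-fold
leave-one-ramp-out cross-validation: `mean_r2` is the coefficient of
determination between predicted and cued joint angles on held-out ramps
(after median-of-three smoothing), averaged over DoFs, folds and repeats
(`n_cells` = 2 repeats × 3 folds × 3 DoFs). Here the model-based neural
set recovers corrupted decompositions better than raw spike-count
regression (AM2); TD features sit near ceiling because the simulated
mixture is stationary and clean — see `docs/methods.md` for what this
synthetic world does and does not show about real recordings.

The same pipeline is scriptable from the shell:

```bash
mukin simulate --seed 7 --out session_dir/
mukin extract-td --session session_dir/ --out td.csv
mukin extract-neural --session session_dir/ --kind AM2 --out am2.csv
mukin fit-model --session session_dir/ --test-ramps 0:2,1:0,2:1 --out model_dir/
mukin evaluate --session session_dir/ --kinds TD,AM2,PROPOSED --repeats 10 --seed 7 --out report.csv
mukin compare --report report.csv --out summary.csv
```

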