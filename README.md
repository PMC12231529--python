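# tremorstage

Staging **fatigue-induced physiological tremor (FIPT)** from multimodal
muscle sensing: surface EMG, accelerometer mechanomyography (MMG_ACC), and a
vision-based muscle cross-sectional-area feature (MMG_CSAC).

FIPT is a reversible 8–14 Hz oscillation that grows as muscle fatigue
accumulates. Its classic myoelectric signature is a rising EMG
root-mean-square amplitude together with a falling EMG median frequency.
`tremorstage` implements a five-stage tremor-progression classifier for
experiment protocols in which a participant performs five task epochs
separated by fatigue-inducing exercise, so that epoch number k serves as the
tremor-level label k ∈ {1,…,5}.

The package is aimed at movement-science and rehabilitation-engineering
groups who record 8-channel EMG armbands on the upper arm and forearm,
tri-axial accelerometers on both segments (500 Hz), and a camera (50 fps)
observing fiducial markers on a forearm armband.

## What it computes

**Vision-based cross-sectional area (the novel sensing channel).** Two
square fiducial markers ride on the armband in each of two orthogonal camera
views. Per frame, the Euclidean distance between marker centroids in a view
tracks one girth axis; the known marker edge (25 mm) converts pixels to
centimeters. Treating the top-view distance as an ellipse's major axis *a*
and the side-view distance as the minor axis *b*, the forearm cross-section
is approximated by `Area = π (a/2)(b/2)`, and the mechanomyographic feature
is the relative change against rest:

```
MMG_CSAC(i) = (Area_i − Area_rest) / Area_rest
```

**Preprocessing.** EMG: DC-offset removal, second-order Butterworth
band-stop around 50 Hz, full-wave rectification, linear envelope.
Accelerometers: signal magnitude vector
`MMG_ACC = √(ax² + ay² + az²)`. CSA: moving-median outlier removal plus
fifth-order Savitzky–Golay smoothing. All channels are resampled onto a
shared 250 Hz timeline and standardized to zero mean, unit variance.

**Classifier.** A BiLSTM-GRU sequence network: bidirectional LSTM (50
hidden units per direction, sequence output) → dropout 0.5 → GRU (50 units,
final-state readout) → dropout 0.5 → dense → softmax over the 5 levels.
Training minimizes weighted cross-entropy
`−(1/L) Σₙ Σₘ wₘ tₙₘ ln yₙₘ` with Adam (lr 10⁻³, piecewise ×0.1 every 10
epochs), L2 weight decay 0.01, batch size 64, and global gradient-norm
clipping at 1. The network, including backpropagation through time, is
implemented directly on numpy arrays and is reproducible from a single
integer seed.

**Evaluation.** Confusion matrices, one-vs-rest per-class
precision/recall/F1, overall accuracy, macro averages, and a feature-set
ablation comparing four modality combinations (set 1: EMG+ACC+CSAC,
19 input series; set 2: EMG+ACC, 18; set 3: EMG+CSAC, 17; set 4: ACC+CSAC,
3) on one identical train/test split.

Because human recordings of this kind are rarely shareable, the package
ships a first-class synthetic cohort generator (`tremorstage.simgen`) that
reproduces the fatigue structure — monotone RMS rise, median-frequency
fall, 8–14 Hz tremor growth, CSA elevation — and can render its CSA series
back into per-frame marker observations, so the entire pipeline is testable
end to end.

## Worked example

```python
import numpy as np
import tremorstage as ts
from tremorstage import dataset as ds, classifier as clf, signalprep as sp

cfg = ts.SimulationConfig(n_participants=6, seed=42)
windows = []
for i in range(cfg.n_participants):
    rec = ts.simulate_recording(cfg, f"P{i+1:02d}")
    channels = ts.preprocess_recording(rec)        # 19 channels @ 250 Hz
    bounds = sp.convert_boundaries(rec.epoch_boundaries, rec.fs_emg, channels.fs)
    for label, seg in ds.label_by_epoch(channels, bounds):
        windows += ds.window_slice(seg, label, window_length=250, n_windows=20,
                                   seed=1000 * i + label,
                                   source_id=f"P{i+1:02d}/ep{label}")

train_w, test_w = ds.split_train_test(windows, seed=42)      # stratified 9:1
X_tr, y_tr, _ = ds.stack_windows(train_w)
X_te, y_te, _ = ds.stack_windows(test_w)

net = clf.NetworkConfig(n_features=19, max_epochs=15, seed=42)
model = clf.train(clf.build_network(net), X_tr, y_tr, net)
pred, _ = clf.predict(model, X_te)
print(f"held-out accuracy {np.mean(pred == y_te):.3f} on {len(y_te)} windows")
print(f"loss {model.history[0]:.3f} -> {model.history[-1]:.3f}")
```

Output:

```
held-out accuracy 1.000 on 60 windows
loss 1.667 -> 0.059
```

The first loss value sits near ln 5 ≈ 1.609 (chance level for five classes,
plus the L2-free cross-entropy of a freshly initialized network) and decays
as the network separates the levels; on the well-separated synthetic
profiles the held-out windows are classified essentially perfectly.

A CLI mirrors the library (`tremorstage simulate | csa | preprocess |
train | evaluate | ablation`); run `tremorstage --help`.

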