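# Methods

This note records the modelling choices behind `ictalnet`, the
defaults and why they were chosen, and what the test suite does and
does not establish.

## Pipeline

The detector treats one EEG *window* as the unit of classification.
Per class, all records are concatenated ("chained") in lexicographic
filename order and the chained signal is segmented with a rectangular
sliding window (length ω, overlap ϑ, both in samples); windows may
straddle record boundaries, which is deliberate — segmentation
operates on the chained signal, not per record.  The final partial
window is dropped, never padded: the start/end closed forms only
define full windows, and a padded tail would mix zero samples into
the statistics.  Coordinates are 1-based inclusive inside the
windowing module so tests can assert the closed forms verbatim;
slicing converts at the array boundary.

Each window yields two feature blocks.

**Scalogram block.**  The complex Morlet CWT (`cmor1.5-1.0`:
bandwidth 1.5, centre frequency 1.0 cycles; the Morlet
parameterisation is exposed in the config because no single
convention is universal) is evaluated on 128 logarithmically spaced
scales covering pseudo-frequencies 0.5–85 Hz — delta through gamma,
stopping below the 86.8 Hz Nyquist limit of the 173.61 Hz sampling
rate.  Log spacing matches the transform's constant-Q resolution.
The magnitude matrix (scales × time, small scale = high frequency at
row 0) is resampled bilinearly to a square single-channel image and
min–max normalised per image to [0, 1].  Per-image normalisation
feeds the autoencoder a fixed input range and makes PSNR well
defined, at the cost of discarding absolute amplitude — the
statistical block retains it.  A constant magnitude matrix has no
dynamic range and renders as an all-zero image with a warning.

**Autoencoder.**  The canonical architecture compresses 256×256×1
through five stride-2, 3×3, same-padded convolutions with 16, 32,
64, 128 and 255 filters to an 8×8×255 bottleneck and mirrors the
stack with transposed convolutions back to 256×256×1.  Kernel 3×3
and stride 2 are the unique hyperparameters consistent with the
reference per-layer parameter counts and output shapes, which
`parameter_report` reproduces symbolically (391,167 encoder and
390,913 decoder trainable parameters); the 255-filter bottleneck is
kept verbatim because the counts confirm it.  Hidden activations are
ReLU, the output layer a sigmoid; the loss is mean squared
reconstruction error (the averaged squared reconstruction norm),
consistent with PSNR reporting, minimised with Adam.  One
autoencoder is trained per scenario on that scenario's training
images (training per class was the alternative; a single model keeps
the latent space shared across labels).  Reconstruction PSNR is
reported on both the training and held-out split, capped at 100 dB
when the MSE is exactly zero.  The implementation is NumPy: the
transposed convolution is the exact linear adjoint of the strided
convolution, so the gradient pair is self-consistent, and all
gradients are finite-difference-checked in the test suite.

**Statistical block.**  Sixteen per-window statistics in a fixed
order.  Conventions that needed fixing once: variance and standard
deviation use the sample (N−1) normalisation and σ = √variance;
kurtosis and skewness are the non-excess standardised moments (a
Gaussian has kurtosis 3); crest factor uses the signed maximum while
peak-to-RMS uses max |s| — two intentionally distinct features;
clearance factor is max |s| / (mean √|s|)², the standard definition.
A constant window (σ = 0) returns 0 for skewness/kurtosis with a
warning rather than NaN, keeping feature matrices finite for
degenerate synthetic configurations.

**Fusion.**  Bottleneck codes are reduced to 128 principal
components.  PCA is fitted on the training split only — fitting on
all windows would leak held-out information through the projection —
using the exact full SVD with a deterministic sign convention (each
component's largest-magnitude loading is positive).  The statistical
features are z-scored with training-split mean/σ before
concatenation: their raw scales span orders of magnitude (energy vs
skewness) and would dominate the classifier input otherwise.  The
hybrid vector is the 128 latent components followed by the 16
statistics; both halves must carry the same window index, and a
mismatch is a hard error, because the fusion's whole point is
aligning two views of the same EEG packet.

**Classifier.**  A 128-unit LSTM (standard f/i/o gating with a tanh
candidate; forget-gate bias initialised to 1) with a dense softmax
readout, trained 50 epochs, batch 32, Adam, categorical
cross-entropy.  The 144-dimensional hybrid vector is presented as a
single time step of width 144 (`framing="vector"`), the conventional
way to feed one feature vector to a recurrent layer.  The
alternative `framing="scalar"` — a length-144 sequence of scalars —
is implemented and config-selectable, but it is not the default: in
experiments on the synthetic corpus the scalar framing prevents the
latent block (the first 128 steps of the sequence) from reaching the
readout through the recurrence, collapsing the latent-only arm of
the ablation to near-chance while a linear probe on the same
features classifies well.  A from-scratch per-gate reference cell
(`cell_step`) transcribes the gate equations literally and is
cross-checked against the vectorised training path.

**Evaluation.**  Scenarios are hyphen-separated groups of class
letters; letters within a group merge into one label (15 catalogue
scenarios from binary to five-class).  The default split is
stratified 80/20 at the window level after chaining, mirroring the
chain-then-window order; because adjacent windows overlap by ϑ
samples, windows sharing samples can land on both sides, so a
record-level split mode (partition records first, then chain and
window each side) is provided for leakage-free estimates.  Binary
problems use the seizure (last) group as the positive class for
precision/recall/F1; multi-class problems report macro averages over
one-vs-rest counts — chosen over micro averaging because per-class
sensitivities are reported alongside and macro treats the classes
symmetrically.  A class with zero support in the test split yields
NaN sensitivity and is excluded from macro averages with a warning.
The ablation retrains the classifier on latent-only (128), stats-only
(16) and fused (144) features with identical splits and seeds across
arms (asserted via a split checksum), isolating the feature set as
the only difference.

## Synthetic corpus

The generator emulates the corpus metadata (five classes, 100 records
of 4097 samples at 173.61 Hz) and a deliberately simple morphology
per class:

* background: Gaussian white noise through a first-order IIR lowpass
  (pole 0.95), rescaled to σ = 1 — a cheap 1/f-like spectrum;
* Z / O: a 10 Hz alpha component with slow random amplitude
  modulation, amplitude 1.0 (eyes open) vs 2.5 (eyes closed);
* N / F: a 6 Hz background component plus Poisson-timed biphasic
  raised-cosine spikes of 70 ms (the canonical interictal spike
  width), amplitude 5, at 1/s for N and 2/s for F — F lies in the
  epileptogenic zone, so it is made similar to N but distinguishable
  by rate alone;
* S: an 8-amplitude rhythmic discharge at 4 Hz with a weak second
  harmonic over reduced alpha.

Amplitudes are unitless; no calibration to physical microvolts is
attempted, and all morphology parameters are stand-ins chosen for
plausibility, not fits to the real corpus.  By construction a plain
per-record energy threshold separates S from Z (a tested generator
property), and window counts, shapes and label balance match the real
corpus layout.  What the generator does **not** emulate: multi-channel
structure, artifacts (EMG, eye blinks), non-stationary background
drift, and — importantly — the real corpus's balance between
time–frequency structure and simple statistics.  Passing the
end-to-end tests therefore demonstrates that the pipeline is wired
correctly and can exploit both feature blocks, not that the real-data
accuracies would be reproduced; running on the real corpus requires
downloading it and pointing `--data-dir` at the ASCII files.

## Problem sizes and profiles

The default configuration is the full study geometry (100
records/class, 256×256 scalograms, the five-layer autoencoder, 128
LSTM units, 50 epochs).  The desk-scale profile used by the tests and
the acceptance script — 20 records/class (83 windows per class),
64×64 scalograms on 64 scales, a three-layer (8, 16, 32) autoencoder
trained 10 epochs, a 32-unit LSTM trained 20 epochs, three seeds —
is the package's chosen compromise between statistical resolution
(83-window test sets resolve accuracy to ~1.2 points) and a
single-core run of a few minutes, while exercising every stage of
the full pipeline unchanged.

## Numerical and reproducibility choices

* One master seed deterministically derives per-stage seeds (CRC-based
  mixing, all below 2³¹), so any stage is reproducible in isolation.
* Convolution padding follows the asymmetric "same" convention (extra
  pad bottom/right); image sizes are powers of two so every stride-2
  stage halves exactly.
* Glorot-uniform initialisation for dense/conv kernels, orthogonal
  for the recurrent matrix; Adam with the standard (0.9, 0.999, 1e-8)
  moments and learning rate 1e-3 throughout.
* PCA requests more components than min(n_train − 1, latent dim) are
  reduced with a warning rather than rejected.
* All-equal scalogram pixels, constant windows and zero-support
  classes degrade with warnings, never NaNs.

## Limitations

* Benchmark accuracies reported on the real corpus are not reproduced
  here; they require the external download, and the original
  train/test protocol is not fully specified (split proportions and
  PCA fitting scope are unstated — train-only fitting is implemented,
  which may be stricter than the original).
* The window-level split is the default for fidelity to the
  chained-then-windowed design but optimistically biased under
  overlap; use `split="record"` for conservative estimates.
* The NumPy networks are single-threaded CPU code sized for
  desk-scale experiments, not a GPU training stack.
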