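# eegfp

Universal, privacy-preserving EEG-based authentication.

A convolutional identification network is trained once on a cohort of
subjects; its dense identification head is then discarded, and the remaining
convolutional stack becomes a fixed-length *fingerprinting* function `f`.
Because `f` works for any EEG sample — including subjects never seen during
training — enrollment of a new user needs no retraining: the system stores
`s = f(a)` (never the raw signal `a`) and verifies a claim by accepting iff
`distance(s, f(a')) <= threshold`, with the threshold calibrated at the
equal-error-rate (EER) point of a DET curve.  A Gram-Schmidt orthogonal
forward search reduces the number of required electrodes by scoring, at each
step, every remaining channel after projecting out the signal content of the
channels already selected.

## What is in the box

| module | role |
| --- | --- |
| `eegfp.signal_io` | EDF and NPZ recording I/O, 10-10 montage with a 20-label commercial subset, versioned JSON fingerprint stores |
| `eegfp.preprocess` | per-channel min-max scaling, Gram-Schmidt orthogonalization, sliding/sampling-window augmentation into `eta x T x |C|` tensors |
| `eegfp.fingerprint_model` | the CNN classifier (pure numpy, CPU), its training loop, and the fingerprint split |
| `eegfp.channel_selection` | orthogonal greedy forward channel search with a pluggable accuracy scorer |
| `eegfp.authentication` | enrollment store, Euclidean/Manhattan/cosine distances, threshold verification |
| `eegfp.evaluation` | genuine/impostor trials, FAR/FRR, DET curves, EER calibration, seen/unseen four-case accuracy matrix |
| `eegfp.synthetic_data` | reproducible multi-subject EEG-like cohorts with controllable separability and redundancy |
| `eegfp.cli` | `simulate / train / select-channels / enroll / verify / evaluate / full-protocol` commands |

The default augmentation parameters are `T=160`, `delta=4`, `eta=20`,
`Delta=8` (so `Gamma = (eta-1)*delta + T = 236` samples per input, and a
60 s recording at 160 Hz yields 1171 overlapping inputs).  The default
network is three 3x3 conv blocks (16/32/64 filters, ReLU, 2x2 max-pooling)
followed by dropout 0.25 and a dense-128 + dense-n softmax head, trained
with RMSprop at 1e-4 for 30 epochs (batch 64).  All of this is config-driven.

Note on the cosine metric: the classical cosine *similarity* is large for
similar vectors; to keep the accept-if-small rule of the verification
function, `eegfp` uses `1 - similarity` as the cosine distance.

## CLI walkthrough

```bash
# a synthetic 16-subject cohort, two sessions each
eegfp simulate --n-subjects 16 --n-channels 3 --duration-s 30 --seed 1 --out data/

# train the identification CNN on the cohort
eegfp train --cohort data/ --seed 1 --out run/

# orthogonal forward channel search over a label subset
eegfp select-channels --cohort data/ --search-space CH00,CH01,CH02 \
    --max-channels 2 --orthogonalize --seed 1 --out run/

# enroll and verify (exit code 0 = accept, 1 = reject)
eegfp enroll --store store.json --id alice --recording data/S000_s0.npz \
    --model run/model --channels CH00,CH01,CH02
eegfp verify --store store.json --claim alice --recording data/S000_s1.npz \
    --model run/model --channels CH00,CH01,CH02 --distance cosine --threshold 0.275

# the whole study: Alpha/Beta split, training, EER calibration, four-case report
eegfp full-protocol --seed 1 --out report/
```

Real recordings in EDF (one shared sampling rate, continuous signal) are
read with channel labels normalized to bare 10-10 names (`"Oz.." -> "Oz"`),
so selections transfer across datasets.

## Notes

- Double precision is used for all signal processing; the network trains in
  float32 for speed.  Runs are deterministic given the seed.
- The enrollment store never contains raw signals or model inputs — only
  fixed-length fingerprint vectors plus enrollment metadata, bound to the
  producing model version.
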