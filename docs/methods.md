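# Methods

## The decoding problem

In a frequency–phase–space SSVEP interface, every command is a triple
(frequency, phase, fixation position). The first two dimensions are
temporal: a flicker modulated at frequency f with initial phase φ evokes a
parieto-occipital response with spectral peaks at f and its harmonics,
phase-locked to the stimulus with a roughly fixed visual latency. The third
dimension is spatial: because the retina maps retinotopically onto visual
cortex, moving the fixation point relative to the flicker shifts which part
of the visual field the flicker occupies, and hence the amplitude and phase
topography of the response across the scalp. Decoding the spatial dimension
is what makes electrode density matter.

## Synthetic data generator

The generator produces epochs with exactly the statistical structure the
decoder exploits, so the full stack can be validated without recordings.
One trial at stimulus code (f, φ, fixation) is

    x_ch(t) = a · Σ_{h=1..Nh} A α^(h−1) g_ch(fixation, h)
              · sin(2π h f (t − τ) + h φ + ψ_ch)  +  η_ch(t)

with the following components and defaults:

- **Latency τ** — 0.140 s nominal, drawn per trial with SD
  `latency_jitter` = 1 ms. SSVEP latency is quite stable across trials
  (phase coding with 0.35π steps would be impossible otherwise); 1 ms
  perturbs the fundamental phase by ~3° at 10 Hz, a mild but nonzero
  realism term. The per-trial amplitude factor `a` is lognormal with 10%
  SD. In noiseless mode (`target_snr_db=None`) both jitters are disabled
  and the trial is the deterministic evoked component — that is the mode
  used for exactness checks.
- **Harmonics** — Nh = 5 with geometric amplitude decay α = 0.5.
- **Spatial gain g** — one von-Mises-like blob per (fixation, harmonic
  band) on the unit head direction sphere:
  `amp · exp(κ (cos θ − 1))` about a center direction. Right/left
  fixations lateralize the harmonic-band blob toward the corresponding
  hemisphere (mirrored), a down fixation uses a broad (κ = 4)
  inferior-occipital fundamental blob, an up fixation a concentrated
  (κ = 16) superior-parietal one, center a symmetric medial-occipital
  blob. These reproduce the qualitative topography classes the decoder
  must separate, not any quantitative map.
- **Phase gradient ψ_ch** — a linear phase ramp across electrode
  positions, 0.12 rad/cm, along a fixation-specific direction; gives each
  fixation a distinct phase topography.
- **Background noise η** — per-channel 1/f^β spectra (β = 1) mixed across
  channels by the symmetric square root of `exp(−d/λ)` with λ = 3 cm, so
  interchannel correlation decays with electrode distance; plus 10%
  uncorrelated sensor noise.
- **SNR calibration** — the noise scale is solved per realization so that
  the narrow-band SNR (target bin over the mean of its ten 1-Hz
  neighbours) measured at the strongest-fundamental channel equals
  `target_snr_db` exactly, accounting for the noise component inside the
  target bin. Default 12 dB, in the range typically reported for
  single-trial SSVEP at the best parieto-occipital electrode. Trial
  averaging across blocks raises the measured value by ~10 log10(Nb) dB,
  as it should.

What the generator does **not** emulate: ocular/muscle artifacts,
nonstationarity across blocks, inter-subject variability, volume-conduction
forward physics, non-sinusoidal response waveshape, and any quantitative
amplitude/phase values. Passing tests therefore demonstrate algorithmic
correctness and qualitative behaviour (density, window, SNR trends), not
recorded-data performance figures.

## Montages

Coordinates are idealized 10-5 positions on a standard head surface
(centimetres), shipped as editable CSV/plain-text data. The four decoding
configurations (66/256, 32/128, 21/64, 9/64) are posterior subsets with
counts forced and nesting enforced (9 ⊂ 21 ⊂ 66; 32 ⊂ 66). The 9/64 list is
the classic baseline set {Pz, POz, Oz, PO3–PO6, O1, O2}. Mean
nearest-neighbour distances of the shipped caps: 1.46 cm (256), 2.0 cm
(128), 3.1 cm (64). The 66/32/21 identities are a documented stand-in: the
source hardware's exact lists are not public, so users can replace the data
files.

## Preprocessing

Epochs are taken at [onset + 140 ms, onset + 140 ms + window), downsampled
to 250 Hz by polyphase decimation (downsample first, then filter), and
decomposed by a bank of zero-phase forward–backward Chebyshev-I bandpasses,
order 4 with 0.5-dB design ripple per direction, subband m spanning
[m·8 − 2, 90] Hz. The 0.5-dB ripple keeps the net two-pass passband
deviation within ±1 dB; a 1-dB design would exceed it. Filtering is applied
to the full-length epoch; decoding windows crop afterwards, so very short
windows (down to 0.02 s) never meet filter edge effects.

## TDCA decoder

Training trials are delay-embedded with order l = 4 (stacking lags 0..l;
training epochs retain l extra samples so no padding occurs), then
augmented along time with their projection onto the span of
sin/cos(2π h f t), h = 1..5, of the class frequency. Filters W (D = 8
columns per subband) maximize the Fisher ratio of between-class to
within-class scatter of the augmented trials; templates are the filtered
class means. A test trial is embedded with zero padding for the
unavailable trailing samples (and, for windows shorter than the training
window, for the missing tail), augmented per candidate class, and
correlated with that class's template on the flattened (component-major)
filtered matrix; subband correlations fuse as Σ_m (m^−1.25 + 0.25) r²_m.
Ties in the argmax resolve to the lowest target id. Numerical choices: the
scatter matrices accumulate in single precision (their sampling error
dominates float32 rounding by orders of magnitude) with a ridge
ε = 10⁻⁶·tr(Sw)/rows plus a small absolute floor, and the generalized
eigensolver retries with a 100× larger ridge if the within-class scatter is
numerically indefinite; trials are internally sorted by class frequency so
the reference projections apply to contiguous blocks. The ensemble-TRCA
baseline uses per-class filters maximizing inter-trial covariance,
concatenated across classes, with the same filter bank and fusion weights.

On this generator the TRCA baseline scores a few points *above* TDCA
(unlike on recorded EEG): the synthetic evoked component is almost
perfectly reproducible across trials, which is the ideal regime for
reproducibility-based per-class filters, whereas TDCA's advantage on real
data comes from temporally structured interference that delay-embedding
whitens. Consistent with that reading, raising the noise exponent to β = 2
closes the gap, and each TDCA ingredient (embedding, reference projection)
improves its own accuracy. The comparison test asserts non-inferiority
within an 8-point band rather than strict superiority.

## Dynamic stopping

Scores are computed at windows 0.1–0.5 s (one TDCA model per window in the
canonical pipeline; a single long-window model with zero-padded scoring is
also supported). At the k-th window the fused features are weighted by
c_k = (k/50)²; a label is emitted once Ts > −(ρt_max − ρt_2max), else the
0.5-s decision is adopted. The margin uses the *weighted* features (the
printed confidence denominator 50 with the 10⁻⁵-scale threshold grid only
makes dimensional sense that way); `weighted_gap=False` switches to
unweighted margins. The sweep grid is Ts = −s·10⁻⁵/2, s = 1..50.

## Scaled problem sizes

Property-style checks run the 200-class task with 4 blocks (3 training
trials per class, one test block) at 0.2 s: electrode-density ordering
(66/256 ≥ 21/64 ≥ 9/64) over 20 seeds on the shared 66-channel data;
window-length (0.1–0.5 s) and SNR (6/12/18 dB) monotonicity on the 9/64
montage over 20 seeds; dynamic stopping on the 40-class task over 20 seeds.
The dynamic-stopping comparison runs at a 20-dB SNR rather than the 12-dB
default: early stopping only pays off when short windows are already
informative, and on the scaled-down montage 20 dB is what reproduces the
high short-window accuracy of the full-density, fully-trained system the
published stopping curves were measured on. At near-chance short-window
accuracy the confidence margin carries little information and the dynamic
rule cannot beat the best fixed window.
These sizes keep every check reproducible on a laptop while leaving the
observed effects far larger than their seed-to-seed variability.
`scripts/acceptance.py` uses the same conditions at 5 seeds.

## Known limitations

- Montage channel identities beyond 9/64 are idealized stand-ins.
- The generator's topographies are qualitative; no claim is made about
  absolute microvolt scales or real-data accuracy levels.
- Greedy electrode search refits the decoder per candidate subset
  (faithful to the described procedure) and is O(Nc²) evaluations; use the
  built-in evaluator cache for repeated runs.
- The stopping rule is synchronous (cue-paced); no rejection class.
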