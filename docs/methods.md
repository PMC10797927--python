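# Methods

## Model

`ms2fp` casts MS/MS annotation as token translation. The encoder reads a
spectrum as a sequence of m/z bin tokens; the decoder writes the ascending
set-bit positions of a binary molecular fingerprint. Both sides are standard
post-norm transformer stacks (self-attention, cross-attention in the decoder,
ReLU feed-forward blocks, layer normalization after each residual sum), with a
linear projection and softmax over the decoder vocabulary producing next-token
probabilities.

### Spectrum tokenization

Fragment m/z values are binned at a constant interval over a closed range
(defaults: 0.01 Da over [50, 1000] Da, giving 95,000 bins plus a padding
token). The bin index is `floor((mz − mz_low)/interval)` with a 1e−9 additive
guard so exact bin edges are stable against floating-point subtraction error;
the upper range edge maps to the last bin. Fragments outside the range are
dropped, the survivors' intensities are normalized to unit sum, and the
fragments are ordered by descending intensity with ties broken by ascending
m/z (a determinism choice; nothing downstream depends on tie order except
reproducibility). Duplicate bins are kept as separate sequence elements.

The tokenized precursor is prepended at rank 0. Its pseudo-intensity is either
the spectral entropy −Σ pᵢ ln pᵢ of the original peak list (natural log;
computed before the out-of-range drop, since entropy is a property of the
spectrum rather than of the tokenized subset) or a constant, default 2 —
deliberately larger than any unit-sum fragment intensity, so the precursor is
always the "loudest" element. The precursor's pseudo-intensity is not part of
the fragments' unit sum.

Spectra longer than `max_seq_len` (default 512) keep the precursor plus the
most intense fragments; the kept fragment intensities are renormalized so the
unit-sum invariant continues to hold.

### Intensity-weighted positional encoding

Encoder inputs are `embedding(token) · sqrt(d_model) + PE`, then dropout,
where

    PE(pos, 2i)   = sin(int · pos / 10000^(2i / d_model))
    PE(pos, 2i+1) = cos(int · pos / 10000^((2i+1) / d_model))

with `pos` the 0-based intensity rank and `int` the pseudo-intensity. Two
details are worth flagging:

* The cosine column uses exponent `(2i+1)/d_model`, not the classic
  `2i/d_model` shared by the sin/cos pair. This is implemented as given; a
  `classic_pe` switch restores the textbook pairing (with `int ≡ 1` and
  `classic_pe` on, the encoding reduces exactly to the classic sinusoidal
  form, which is property-tested).
* The sinusoid argument is the *product* of intensity and rank, so doubling
  intensity at fixed rank equals doubling rank at fixed intensity; position 0
  (the precursor) always encodes to (0, 1, 0, 1, …) regardless of intensity.

Decoder-side bit tokens receive embeddings only — their ascending order is a
grammar enforced at decode time, not a geometry worth encoding. The
`sqrt(d_model)` embedding scale is a conventional choice recorded in the
checkpoint's configuration echo.

### Decoder vocabulary

Fingerprint bit b maps to token b+3; tokens 0/1/2 are padding, start, end. A
target sequence is `[start, b₁+3, …, b_k+3, end]` with strictly ascending bits.

## Training

Teacher forcing: decoder input is the target shifted right; the loss compares
each position's distribution with the next true token. The loss is
label-smoothed cross-entropy (smoothing ε puts 1−ε on the true token and
ε/(K−1) on each other token; default ε = 0.1), averaged over non-pad
positions. Optimization is Adam (defaults: learning rate 1e−4, betas
(0.9, 0.98), no weight decay, no scheduler); batches are padded to the batch
maximum and pads are masked out of attention and loss. After every epoch whose
mean loss improves on the best seen, the weights are written to the configured
output directory, so the on-disk checkpoint always corresponds to the minimal
training loss; `train` also returns the model restored to those weights. No
train/validation split is imposed — checkpointing is on training loss, with
the split left to the user's YAML if wanted.

A single seed controls weight initialization, batch shuffling and dropout, so
CPU runs are bit-reproducible.

The network and its backpropagation are implemented directly in NumPy
(float64). Gradient correctness is established by finite-difference tests over
every parameter tensor; the comparison tolerance is loose enough (1e−3
relative) to absorb the inherent inaccuracy of finite differences at ReLU
kinks, while typical entries agree to ~1e−7.

## Inference

Beam search starts from the start token and, after emitting bit token t,
admits only tokens strictly greater than t plus the end token. This hard
admissibility mask guarantees every hypothesis decodes to a valid ascending
bit set and concentrates beam capacity on the grammar the model was trained
on. Hypotheses are compared by raw cumulative log probability (a length
penalty exists but defaults off). Completed hypotheses move to a finished pool
that partial hypotheses cannot evict; since log probabilities only decrease
with length, the search stops early once no live hypothesis can beat the
retained pool. With beam width at least the number of admissible sequences,
the search is exhaustive (tested against brute-force enumeration on a 4-bit
vocabulary). Width monotonicity — a wider beam never returning a worse best
score — holds empirically on trained, peaked models and is tested there, but
it is not a theorem of beam search and can fail on near-uniform untrained
models.

`max_bits` (default: the fingerprint length) caps the number of emitted bits;
a hypothesis closed by the cap rather than by its own end token triggers a
warning.

## Evaluation

Candidates are ranked by Tanimoto similarity |A∩B|/|A∪B| between the predicted
and candidate bit sets (defined as 1 when both are empty); ties are broken by
identifier so rankings are deterministic, and a rank-1 tie counts as correct
only if the true candidate wins the tie-break. Compound identity is compared
on the first 14 characters of the InChIKey when identifiers are InChIKeys (the
2D-skeleton block), else on the exact string. Per-group summary tables report
n, mean, sample (n−1) standard deviation and median of top-hit Tanimoto
scores; a single observation reports sd 0 since the sample convention is
undefined there. `threshold_annotations` applies a closed ≥ cutoff.

## Synthetic libraries

The fixture generator draws, per compound, a sparse fingerprint (each bit
active with probability 0.15, mimicking ECFP bit density; at least one bit is
forced) and emits one fragment peak per active bit at a fixed bin center under
an injective bit→m/z map, plus a precursor 5 Da above the largest fragment.
Intensities are uniform on [0.2, 1.0] with multiplicative log-normal jitter
(default sd 0.05). Defaults are 50 compounds with 64-bit fingerprints over
50–150 Da at 0.1 Da bins.

Because the bit→peak map is injective and noise never moves a peak out of its
bin, the inverse problem is exactly solvable: a small model (d_model 64, one
layer per side) memorizes the library to Tanimoto 1.0 within about 60 epochs.
That is the point — these libraries isolate the correctness of tokenization,
training, decoding and ranking from the hardness of real fragmentation
chemistry. Passing them says the machinery works; it says nothing about
annotation accuracy on real spectra, where the spectrum→fingerprint map is
many-to-many, class coverage of the training library dominates performance,
and fragment peaks do not correspond one-to-one with substructures.

## Configuration surface

One YAML file drives everything (`mint-workflow --yaml file.yaml`):

| section | keys (defaults) |
| --- | --- |
| `task` | `train` or `predict` |
| `msp` | `paths`; `min_coverage_fraction` (0.9): a spectrum is admitted iff ≥ this fraction of its peaks lie inside the tokenizer range (closed interval, closed ≥); `precursor_aliases`; `fingerprint_key` (`Fingerprint`) |
| `fingerprint` | `kind` (required: `ecfp`/`maccs`/`custom`), `radius` (2), `n_bits` (2048; fixed 166 for MACCS) |
| `tokenizer` | `mz_low` (50), `mz_high` (1000), `interval` (0.01 Da), `use_entropy` (false), `precursor_pseudo_intensity` (2), `max_seq_len` (512) |
| `model` | `d_model` (512), `n_heads` (2), `n_encoder_layers` (4), `n_decoder_layers` (4), `d_feedforward` (2048), `dropout` (0.1), `classic_pe` (false), `scale_embedding` (true) |
| `train` | `epochs` (10), `batch_size` (8), `label_smoothing` (0.1), `learning_rate` (1e−4), `adam_betas` (0.9, 0.98), `weight_decay` (0), `seed` (42), `output_directory` |
| `predict` | `checkpoint`, `beam_width` (5), `max_bits`, `top_k` (5), `candidates`, `output` |

The resolved configuration is echoed into the output directory as
`config_echo.yaml`; the echo re-parses to an equal configuration, so a run can
be reproduced from its own provenance log. Checkpoints are `.npz` archives
carrying the weights plus the model configuration and token vocabulary, so a
checkpoint is self-describing and prediction validates it against the YAML.

With the default vocabularies, d_model 512 and feed-forward 2048, the model
has 80,168,451 trainable parameters (embeddings included) — the figure
`scripts/acceptance.py` recomputes. d_model and the feed-forward width are
defaults of this package chosen jointly with the printed layer/head counts to
land the total at ≈8×10⁷; both are YAML-overridable.

## MSP dialect choices

Header keys match case-insensitively; the precursor m/z is accepted under
several aliases (`PrecursorMZ`, `Precursor_mz`, …, configurable) because MoNA
and GNPS exports differ. Blocks without a precursor are skipped and counted,
not raised. Malformed blocks (non-numeric peaks, empty peak lists) are dropped
and reported with their block index without poisoning the rest of the file.
Zero-intensity peaks are dropped at parse time — they carry no rank or
normalization mass. Pre-computed fingerprint bits ride in a configurable
header (default `Fingerprint:`) as comma-separated ascending integers and take
precedence over SMILES/InChI; SMILES is preferred over InChI when both parse.
MACCS keys are re-indexed to 0-based positions over 166 keys so all
fingerprint kinds share one token arithmetic.

## Known limitations

* Memorization-style fixtures cannot probe generalization across compounds;
  real benchmarking needs real libraries and a held-out design.
* Pure-NumPy training is practical at desk scale (seconds for the fixture
  libraries) but orders of magnitude slower than a GPU framework at the
  default 8×10⁷-parameter configuration.
* Neutral-loss and m/z-difference tokens are out of scope, as are consensus
  spectra, adduct handling and count fingerprints.
* The `device: gpu` setting is accepted for configuration compatibility but
  execution is CPU-only.
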