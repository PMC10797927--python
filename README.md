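# ms2fp

Translate tandem mass spectra (MS/MS) into molecular fingerprint bit positions
with an encoder–decoder transformer.

## The problem

In untargeted metabolomics, lipidomics and exposomics, most MS/MS spectra never
match anything in a reference spectral library, so most features in a study go
unannotated. One way past this bottleneck is to predict a *molecular
fingerprint* — a binary vector of substructure indicators such as ECFP or MACCS
keys — directly from the spectrum, and then search that fingerprint against a
structure database (e.g. LipidMaps) by Tanimoto similarity. The top-ranked
candidates become annotation hypotheses even for compounds with no library
spectrum at all.

`ms2fp` treats this as a sequence-to-sequence translation problem:

* **Source sequence** — fragment m/z values tokenized into constant-width bins
  (default 0.01 Da over 50–1000 Da), each paired with its unit-sum-normalized
  intensity; the tokenized precursor m/z is prepended with a pseudo-intensity of
  either the spectral entropy −Σᵢ pᵢ ln pᵢ of the spectrum or a constant 2.
* **Target sequence** — the set-bit positions of the compound's fingerprint,
  emitted in ascending order between start/end sentinels.
* **Model** — a standard post-norm transformer (default 4 encoder + 4 decoder
  layers, 2 attention heads, d_model 512, feed-forward 2048; ≈ 8×10⁷ trainable
  parameters with the default vocabularies) whose encoder-side positional
  encoding is modulated by intensity:

  PE(pos, 2i) = sin(int · pos / 10000^(2i/d_model))
  PE(pos, 2i+1) = cos(int · pos / 10000^((2i+1)/d_model))

  where *pos* is the fragment's rank in descending-intensity order and *int*
  its pseudo-intensity, so abundant ions carry more positional signal.
* **Decoding** — beam search constrained to strictly ascending bit tokens, so
  every hypothesis is a valid fingerprint by construction.
* **Training** — teacher-forced label-smoothed cross-entropy with Adam,
  checkpointing the weights at the minimal training loss, all configured from a
  single YAML file.

The whole network (layers, backpropagation, Adam) is implemented in NumPy; the
only chemistry dependency is RDKit, used to compute ECFP/MACCS fingerprints
from SMILES or InChI strings when MSP blocks don't carry pre-computed bits.

## Worked example

Train a small model on a synthetic library in which each fingerprint bit maps
injectively to one fragment peak (so the inverse problem is well-posed), then
decode the training spectra back to fingerprints:

```python
import numpy as np
from ms2fp.fixtures import FixtureSpec, generate_custom_bit_library
from ms2fp.msp_io import parse_msp
from ms2fp.tokenizer import TokenVocabulary, encode_spectrum, encode_target
from ms2fp.fingerprints import FingerprintSpec, resolve_target_bits, tanimoto
from ms2fp.model import ModelConfig, MintModel
from ms2fp.training import TrainConfig, train
from ms2fp.inference import beam_search

spec = FixtureSpec(n_compounds=30, n_bits=32, seed=1)
msp_text, truths = generate_custom_bit_library(spec)
vocab = TokenVocabulary(mz_low=50.0, mz_high=150.0, interval=0.1)
fp = FingerprintSpec(kind="custom", n_bits=32)

dataset = []
for s in parse_msp(msp_text):
    bits = resolve_target_bits(s, fp)
    dataset.append((encode_spectrum(s, vocab, use_entropy=True), encode_target(bits)))

config = ModelConfig(
    encoder_vocab_size=vocab.vocab_size, decoder_vocab_size=32 + 3,
    d_model=32, n_heads=2, n_encoder_layers=1, n_decoder_layers=1,
    d_feedforward=64, dropout=0.0,
)
model, log = train(dataset, MintModel(config, seed=0), TrainConfig(
    epochs=80, batch_size=10, label_smoothing=0.0, learning_rate=1e-3, seed=0,
))
print(f"best training loss {log.best_loss:.4f} at epoch {log.best_epoch}")

scores = []
for (tokens, _), truth in zip(dataset, truths):
    predicted = beam_search(model, tokens, beam_width=3)[0]
    scores.append(tanimoto(predicted.bits, truth.bits))
print(f"mean training Tanimoto {np.mean(scores):.3f} "
      f"({sum(s == 1.0 for s in scores)}/{len(scores)} exact)")
```

Output:

```
best training loss 0.0439 at epoch 79
mean training Tanimoto 1.000 (30/30 exact)
```

The loss is the mean per-token cross-entropy at the best epoch; a Tanimoto of
1.000 means every decoded bit set equals the true fingerprint — the expected
behaviour when an over-parameterized model memorizes a small, invertible
training set. On real spectra, accuracies depend on how well a compound class
is covered by the training library.

The same pipeline runs from the shell with a YAML file:

```bash
mint-workflow --yaml train.yaml    # parses .msp, trains, exports best-loss checkpoint
mint-workflow --yaml predict.yaml  # beam-decodes fingerprints to a TSV table
```

See `docs/methods.md` for the YAML sections and every tunable parameter.

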