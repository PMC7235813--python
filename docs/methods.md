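# Methods

## Task and model

The task is character-level named-entity recognition in clinical text:
each character of a sentence `C = (c_1, …, c_n)` receives one of 13 BIO
labels (`B-t`/`I-t` for the six clinical entity types Dis, Sym, Test,
Tre, Med, Abn, plus `O`), and contiguous `B-t I-t…` runs decode to typed
entity spans.

The tagger is a three-stage pipeline:

1. **Encoder.** A transformer encoder maps the sentence to hidden
   states `h_1, …, h_L`, one `(n, d)` array per layer.  The input
   embedding is the elementwise sum of token, segment and (learned)
   position embeddings; the task is single-sentence, so a single
   segment id is used throughout, and no boundary tokens are inserted —
   every position is a taggable character.  Each block is a
   post-layer-norm encoder layer: multi-head self-attention and a GELU
   feed-forward of width `4d`, each wrapped in residual + layer norm.
   All layers' outputs are retained, not just the last.

2. **Multi-level fusion.**  For each token independently, the selected
   layers' hidden vectors are fused by multi-head scaled dot-product
   attention *over layers*:

       Q = w_Q h_L + b_Q,   K_l = w_K h_l + b_K,   V_l = w_V h_l + b_V
       head_i = softmax(Q_i K_iᵀ / √d_head) V_i
       E = Concat(head_1 … head_H) w_h + b_h

   The query comes from the token's final-layer state; the key/value
   items are its per-layer states, so each head learns a mixture over
   depths.  Comparison strategies sharing the interface: feature-axis
   concatenation of the selected layers followed by a linear projection
   back to width `d`; the unweighted per-layer mean (sum-average); and
   the plain last layer.

3. **Head.**  `Y = Softmax(w_O E + b_O)` gives per-token distributions
   over the 13 tags; the row argmax is the prediction.  There is no CRF:
   tags are predicted independently, and structured decoders are treated
   as separate baseline systems, not part of this model.

### Interpretation of the fusion step

Written as a single concatenation `H = Concat(h_1 … h_L)`, the fusion
admits two readings: attention over *sequence positions* of a widened
representation, or per-token attention over *layers*.  This package
implements the latter: it types the softmax correctly (the attention
items are the `|subset|` layer vectors of one token), it matches the
motivation of extracting complementary information from different
depths, and it keeps feature-axis concatenation available as a distinct
baseline.  Cross-token interaction happens only inside the encoder.

Two notational choices follow the same reasoning: the scaling
denominator is the per-head key dimension `d_head = d / H` (the
dimension of the vectors whose dot product is scaled), and the query
bias is a bias like any other (some printings call it `b_L`).  Head
splitting is contiguous: the `d`-wide projections are split into `H`
blocks of `d_head`, and concatenation restores width `d` before the
square mixing matrix `w_h`.

The final layer always belongs to the layer subset (the query is built
from it).  Named subsets resolve as `all` = {1…L}, `last k` =
{L−k+1…L}.

## Training

- Loss: mean per-token negative log-probability of the gold tag,
  padding positions masked.
- Optimizer: AdamW (Adam β₁ = 0.9, β₂ = 0.999, ε = 1e-8, with decoupled
  weight decay 0.01 applied to matrix-shaped parameters only — biases
  and layer-norm gains/offsets are not decayed).
- Batches of 32 sentences, shuffled each epoch, padded to the longest
  sentence in the batch; padded keys are excluded from self-attention.
- Dropout (inverted) after the attention and feed-forward sublayers and
  on the fused embedding `E`, during training only.
- Model selection: the checkpoint with the best validation micro-F1 is
  returned; ties keep the earliest epoch.
- Sentences longer than `max_sentence_length` (default 64) are
  truncated; a gold span crossing the cut is discarded whole rather
  than clipped, to avoid fabricating partial entities.

Two training profiles exist.  The *mirrored* profile keeps the
literature geometry (L = 12, d = 768, 12 heads, learning rate 1e-5,
10 epochs, batch 32, dropout 0.3) appropriate for fine-tuning a large
pretrained encoder loaded through the adapter seam.  The *tiny* profile
(L = 4, d = 64, 4 encoder heads, 4 fusion heads, dropout 0.1, learning
rate 2e-3, same batch size and epoch budget) trains from random
initialization at desk scale; the larger step size is what a small
from-scratch transformer needs to converge inside 10 epochs, and 2e-3
was chosen as a conventional small-transformer setting.  The encoder
is trained on the task loss only; masked-language-model pretraining is
out of scope, and pretrained weights enter only through
`load_pretrained_adapter`.

## Synthetic corpus

Real annotated clinical corpora of this kind are private, so the corpus
module generates a synthetic stand-in: template sentences with entity
slots filled from small per-type lexicons, embedded in non-entity
context characters, with exact span offsets recorded at generation
time.

The default recipe is *separable by construction*: each entity type
draws from its own disjoint character pool (so type is decidable from
any single character), and the first two characters of each pool are
reserved for entity-initial positions (so B-vs-I is decidable from the
character as well).  Every BIO tag is then a function of the character
itself, which makes the end-to-end sanity floor a test of the whole
pipeline — data generation, encoding, fusion, optimization, decoding,
scoring — rather than of a small encoder's capacity for positional
reasoning.  Entities are 2–4 characters long, 12 lexicon entries per
type, 24 entity-bearing templates (1–3 slots each) plus 4 entity-free
templates; sentences are i.i.d. given the seed.

What this corpus does **not** emulate: real clinical-character
ambiguity (the same character appearing in entities of different types
and in context), nested or discontinuous mentions, document structure,
label noise, and class imbalance beyond the template mix.  Passing the
learning floor therefore says the implementation is correct and
trainable, not that the architecture reaches any particular accuracy on
real electronic medical records.

## Evaluation

Strict span-level scoring: a predicted span counts only if type, start
and end all match a gold span of the same sentence; each gold span can
match at most once (duplicates cannot double-count).  `P = TP/(TP+FP)`,
`R = TP/(TP+FN)`, `F1 = 2PR/(P+R)`, with any zero-denominator score
reported as 0.  Micro-averaged F1 (counts summed over the six types) is
the headline number; the macro average is emitted for completeness.
Predicted BIO sequences are decoded with the `start-new` repair (an
orphan `I-t` opens a new span); `strict` decoding is available for
debugging model output.  A brute-force quadratic scorer with no data
structure shortcuts serves as an oracle twin in the tests.

## Experiments

The harnesses sweep one factor at a time — assembling method
(multihead / concat / sum-average / last-layer), extracted layer subset
(all / last6 / last4 / last2), or training-set fraction (nested subsets
from a single shuffle) — holding the corpus, splits, encoder geometry
and optimization identical across cells; a configuration hash over the
non-varied settings is logged per grid to make fairness checkable.
Each cell runs `repeats` times with derived seeds and reports the run
with the median test micro-F1 (for three repeats, the middle of the
ranking; for even counts, the lower middle).

## Numerics and determinism

All computation is float64 numpy on a small reverse-mode autodiff
engine written for this package (no deep-learning framework is a
dependency).  Gradients are verified against central finite differences
in the test suite.  Backward closures capture plain arrays rather than
node objects, so graphs are acyclic in the reference-counting sense and
are freed eagerly — this matters for speed and memory in long training
loops.  Parameters initialize as N(0, 0.02²) (layer-norm gains 1,
biases 0).  Softmax and log-softmax subtract the row maximum before
exponentiation.  Every stochastic component (corpus generation,
splitting, initialization, batch shuffling, dropout) is driven by an
explicit integer seed through `numpy.random.default_rng`, so repeated
runs on one platform are bitwise identical.

Problem sizes for the desk-scale checks were chosen to exercise the
full pipeline comfortably on a single CPU: the end-to-end benchmark
trains on 2000 sentences (validation/test 500 each) for up to 10
epochs; the assembling comparison uses 500-sentence corpora with 6
epochs; harness unit tests use 100–200 sentences.

## Known limitations

- Single flat BIO layer: nested and overlapping entities are not
  representable, by design.
- No learning-rate schedule or warmup; the tiny profile can oscillate
  late in training at aggressive learning rates (best-epoch selection
  absorbs this).
- The learned-vs-sinusoidal choice for position embeddings is fixed to
  learned; the adapter seam inherits whatever the external weights
  used.
- Tag-level independence (no CRF) means decoded spans can arise from
  non-canonical sequences; scoring applies the documented repair rather
  than rejecting them.
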