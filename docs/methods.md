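# Methods

## Model family

The package implements one architecture family: a recurrent sequence
autoencoder over tokenized molecule strings. Input and output are one-hot
token vectors over a shared vocabulary (`PAD=0, SOS=1, EOS=2`, then the
chemistry tokens in lexicographic order, so encodings are bit-reproducible).
The encoder consumes the sequence token by token; padded positions are
masked so the carried state at each molecule's own length is the final
state regardless of batch padding.

Latent bridging is configuration-dependent and deliberately minimal:

| configuration | encoder → z | z → decoder |
|---|---|---|
| GRU, m=1, H=L, no attention, plain | identity (*z = h_T*) | identity |
| GRU otherwise | Linear(H·m → L) over concatenated per-layer *h_T* | Linear(L → H·m), split per layer |
| LSTM | Linear(2·H·m → L) over *h_T* ⊕ *c_T* | two Linears(L → H·m) for initial hidden and cell states |
| + attention | context vector concatenated before the projection (which then always exists) | unchanged |
| + variational | two Linears give μ and log σ² from the same pre-latent feature | unchanged |

Design choices that were genuinely open:

* **Multi-layer bridge wiring.** All layers' final states are concatenated
  into one projection, and the decoder's initial states come from one
  linear map (GRU) or two (LSTM), reshaped per layer. This is the natural
  generalization of the single-layer wiring; trends for multi-layer models
  should be read qualitatively.
* **Attention.** Additive self-attention pooling over the top-layer encoder
  step outputs: `score_t = v·tanh(W h_t + b)`, softmax over unmasked steps,
  context = weighted sum. It is the smallest encoder-side mechanism
  consistent with "attention added to the encoder"; decoder-side attention
  is deliberately absent.
* **Decoder inputs** are one-hot tokens, not learned embeddings, matching
  the one-hot framing of the model family.
* **VAE evaluation** uses the mean μ; sampling happens only in training.
* **SOS/EOS/padding.** The decoder starts from SOS and stops at EOS; the
  loss averages over non-PAD target positions (EOS included). These
  conventions are package choices, not constraints of the family.

## Training protocol

Adam at learning rate 0.005, teacher forcing on every training step
(ratio 1.0, no schedule), token-level cross-entropy, and for variational
models + β·KL with constant β (default 0.3). Early stopping acts on
validation loss only between 50 and 500 epochs: stop once the running best
has not improved by more than 0.01 for 5 consecutive epochs. Each
configuration is trained for three seeds; metrics are reported as the mean
with min/max across seeds (the error-bar convention of the experiments).

The validation set is a seeded 10% split. `holdout_validation=False` keeps
the split as a monitoring signal but trains on the full corpus — the right
setting for memorization runs, where the question is whether the model can
store the corpus, not whether it generalizes.

Enumeration modes resample the paired variant every epoch (seeded), so
augmentation presents different strings of the same molecule across epochs.
The vocabulary is built from every string the protocol may present;
canonical-only training additionally harvests tokens from a few seeded
enumerations per molecule, because non-canonical SMILES use structural
tokens (branches, ring reopenings) that a small canonical corpus may lack,
and a model without them could never embed enumerated variants during
latent diagnostics.

## Metrics

All metrics operate on tokens (so `Cl` is one unit), with *n* the input
token count. Mean Similarity scores position-by-position matches over
positions 1..n; positions the reconstruction does not reach score 0, and
reconstruction tokens beyond *n* are ignored — the length-mismatch rule is
a documented package choice. Levenshtein similarity is 1 − LD/n clamped at
0 (LD can exceed n for wildly long reconstructions). Full Reconstruction is
the percentage of token-for-token identical pairs. The token-level edit
distance is verified in the tests against an independent recursive oracle
and against the `edlib` alignment library.

## Latent diagnostics

`minmax_scale` scales per dimension (a constant column maps to zeros) and
is what the per-dimension heatmap view uses. The utilization *classifier*,
however, scales the latent matrix globally (one min-max per model): a
collapsed space is one where every dimension sits near its own constant
across molecules — the striping pattern — and per-dimension scaling would
inflate that jitter to full range and hide the collapse. After global
scaling, a dimension is "low" if its variance is below τ_low = 0.01;
with fraction f of low dimensions, f ≥ 0.9 is posterior collapse,
0.05 ≤ f < 0.9 is selective utilization, else high utilization. The
reference typology is visual, so these thresholds are package choices,
configurable and recorded in every report. A consequence worth noting: the
classification is invariant to whole-matrix affine changes of units, but
*not* to independent per-dimension rescalings — by design, since relative
dimension spread is the signal.

Chemical-similarity probes embed a random background (default 10,000
molecules, or the whole pool with a warning) plus a few test molecules with
their enumerations (4 by default; SELFIES models receive translations of
the enumerated SMILES), fit one PCA on all embeddings jointly (a single
projection, rather than projecting test points into a background-only PCA),
and report two-component coordinates, explained-variance percentages and
within-group vs background pairwise Euclidean distances.

## Synthetic data

The fixture generator samples random token strings over a small organic
alphabet (`[C] [=C] [N] [=N] [O] [=O] [F] [Branch1] [Ring1]`) of bounded
token length (default 3–15) in the package's SELFIES-style dialect and
decodes them into molecules. Because the dialect's derivation rules cap
every bond by the remaining valence, any random string yields a valid
molecule, which is exactly the property that makes download-free corpus
generation possible. Accepted molecules must be pairwise distinct (by
canonical SMILES) and, by default, admit four distinct non-canonical
SMILES (`ensure_enumerable=4`) — emulating curated drug-like sets, whose
multi-atom asymmetric molecules are always enumerable, and guaranteeing
that enumeration-augmented protocols are well-defined on every fixture.

What the fixtures do *not* emulate: realistic pharmacological property
distributions (logP, QED, ring-system statistics), charged or
multi-fragment species, stereochemistry, and corpus scale (thousands, not
millions). Passing tests therefore demonstrate correctness of the
machinery and reproducibility of directional architecture effects at small
scale, not absolute performance on benchmark corpora.

The SELFIES dialect itself is restricted to neutral C/N/O/F/S/P with
single/double/triple bonds, branches and rings; its encoder kekulizes
aromatic input. It is self-consistent (decode ∘ encode preserves the
molecule, verified by round-trip tests) but intentionally not
token-compatible with other SELFIES software.

Loss-trace fixtures provide `improving` traces (each step improves by more
than the early-stopping min-delta) and `plateau_after_k` traces (improve
until step k, then vary within ±0.45·min-delta), which exercise every
branch of the stopping rule deterministically.

## Numerical choices

The NN core is float64 NumPy with a minimal reverse-mode autodiff;
gradients of every architecture variant are checked against central finite
differences (absolute agreement ~1e-7 or better). Weights initialize
uniform ±1/√fan from a per-seed generator; no gradient clipping. Adam uses
the standard bias-corrected moments (β₁ 0.9, β₂ 0.999, ε 1e-8).
Greedy decoding is deterministic; ties in argmax resolve to the lowest
index. Checkpoints round-trip bit-exactly (weights in `.npz`, config,
vocabulary and seed in JSON).

## Problem sizes

The packaged experiment sizes are chosen for single-CPU reproducibility:
memorization uses 50 molecules × 400 epochs (batch 16); the GRU-vs-LSTM
comparison uses 500 molecules × 60 epochs × 3 seeds (batch 64), equal
budgets for both cells. At these scales the GRU-over-LSTM Full
Reconstruction advantage is directional and robust, but absolute rates are
far below what full-scale corpora and GPU-scale budgets produce; only the
direction of the comparison, not its magnitude, should be read.

## Known limitations

* Greedy decoding only; no beam search.
* A constant KL weight; no annealing schedules.
* The dialect cannot encode charged species, radicals, stereochemistry or
  elements outside its subset; corpora containing such molecules must be
  filtered before SELFIES-mode training.
* Single-threaded training; the unrolled-graph autodiff favors clarity
  over speed and is sized for corpora of thousands of molecules.
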