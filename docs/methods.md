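# Methods

## Model

The chemical language model is an autoregressive token model over SMILES
strings. Sequences are laid out as `[BOS] t_1 … t_n [EOS] [PAD]…` with a
fixed content length per corpus (default 100 tokens, the curation cutoff).
The network is: token embedding → `n_blocks` pre-norm residual blocks →
final LayerNorm → linear projection to the vocabulary. Each block applies
LayerNorm, then one independent single-input single-output state-space
system per channel, a per-channel learnable skip `D·u`, a GELU
nonlinearity (tanh form), and a pointwise channel-mixing linear layer that
is the only place channels interact.

Each channel's system is the discrete state-space recurrence
`x_k = Ā x_{k-1} + B̄ u_k`, `y_k = C̄ x_k + D̄ u_k` with zero initial
state. Unrolling the recurrence shows the output is a causal convolution
with the kernel `K̄_k = C̄ Ā^k B̄`; training uses this convolutional form
(executed with FFTs over the whole sequence), generation uses the
recurrence. The two paths are algebraically identical, and the test suite
holds them to 1e-4 relative agreement on random systems and 1e-3 on
trained models; in practice they agree to roughly machine precision.

### State-matrix structure and initialization

The continuous state matrix is the HiPPO-LegS operator
(`A[n,k] = −√((2n+1)(2k+1))` below the diagonal, `−(n+1)` on it). With
`P_n = √(n+½)`, `A + PPᵀ + I/2` is skew-symmetric, giving the
diagonal-plus-low-rank form `A = V (Λ − p q*) V*` with `Re Λ = −1/2`; all
eigenvalues of `A` are `−(n+1) < 0`, so the continuous system is strictly
stable and the bilinear (Tustin) discretization
`Ā = (I − Δ/2·A)⁻¹(I + Δ/2·A)` is contractive. Step sizes Δ are drawn
log-uniformly from `[1e-3, 1e-1]` per channel; B and C are random
(`B ~ N(0,1)`, `C ~ N(0,1/N)`), `D = 1`.

The convolution kernel has two computation paths: direct materialized
matrix powers (the oracle, used by the model for the state sizes it
employs, N ≤ 64), and the structured generating-function path that
evaluates the truncated kernel transform at roots of unity through
Woodbury-expanded Cauchy dot products against `1/(ζ − Λ)` and inverts with
an inverse FFT. The evaluation grid is forced to odd length so the
bilinear pole at z = −1 is never a node. Both paths agree to 1e-6
relative error in the tests.

### Training

All forward and backward passes are explicit NumPy. The design choice that
makes exact hand-derived gradients practical is freezing the state-space
spectrum: Λ, P, Q and Δ stay at their HiPPO initialization and only B, C,
D (plus embeddings, LayerNorm, mixing and output weights) are trained.
The kernel is then bilinear in (B, C), so its gradients are closed-form
contractions against the precomputed power stacks `Ā^l B̄` and `C̄ Ā^l`;
fixed-spectrum training is an established variant in this architecture
family and suffices for every behaviour the package exercises. Gradients
are verified against central finite differences in the test suite.

Optimization is Adam (β = 0.9/0.999, no weight decay) on teacher-forced
next-token cross-entropy; the loss masks PAD targets but scores EOS.
Training can run in float32 (roughly half the CPU time; the default for
the larger runs) or float64. An optional cosine learning-rate schedule
decays the rate to zero over the configured epochs. Fine-tuning continues
training on a small set with early stopping on validation cross-entropy
(patience 5 epochs, tolerance 1e-5; an improvement smaller than the
tolerance counts as no improvement), never alters vocabulary or model
shape, drops molecules not expressible in the pre-training vocabulary with
a warning, and retains the models of the last five epochs for
checkpoint-pooled generation campaigns.

## Tokenization and curation

The tokenizer uses the standard SMILES token classes, in precedence order:
bracket atoms `[...]`, two-digit ring labels `%nn`, the two-letter
halogens Cl/Br, then single characters; concatenating tokens always
reproduces the input. Curation keeps molecules over the element whitelist
C, H, O, N, S, P, F, Cl, Br, I; strips a fixed counter-ion list and then
discards any remaining multi-fragment entry; removes stereochemistry;
neutralizes chemically trivial formal charges by hydrogen adjustment
(discarding molecules that cannot be neutralized this way); canonicalizes
with RDKit; enforces the 100-token cutoff; and deduplicates on canonical
form. Vocabularies store reserved tokens (PAD, BOS, EOS) first and the
corpus tokens sorted, so the mapping is a deterministic function of the
token set and checkpoints are portable.

## Sampling, scoring, selection

Temperature sampling uses max-subtracted softmax of `logits/T`; `T = 0`
is argmax with first-index tie-breaking and never consults the random
stream. Each generation batch owns one seed; per-sequence child streams
are spawned from it so results are independent of batch composition. The
temperature sweep driver covers T = 1.0 … 2.0 in steps of 0.25, and the
campaign planner enumerates (last-5-epochs × 5 temperatures × 10,240
designs) = 256K-design campaigns.

Joint log-likelihoods sum the teacher-forced log-probabilities of all
content tokens plus EOS (BOS is conditioning only) and are invariant to
padding because the model is strictly causal. The bias-corrected score is
the fine-tuned minus pre-trained log-likelihood; ranking is descending
with seeded tie-shuffling. Enrichment is reported as recall@k — actives in
the top k divided by all actives — with precision@k behind a flag.
Prospective selection keeps valid, unique designs novel w.r.t. the
fine-tuning set, ranks by fine-tuning log-likelihood, keeps the top 5,000,
splits at 60% Bemis–Murcko-scaffold ECFP Tanimoto similarity to the
fine-tuning set, groups each side by nearest training molecule, and keeps
the top bias-corrected scorer per group.

## Evaluation conventions

Validity, uniqueness and novelty all use the total generated count as
denominator. Invalid strings are classified with precedence branching
(unbalanced parentheses) > ring (odd ring-label counts) > bond
(syntactically balanced but failing RDKit sanitization, i.e.
valence/bond-order violations, including kekulization failures) > other
(unparseable). Property profiles use RDKit descriptors (Crippen logP, QED,
Bertz complexity, synthetic accessibility and natural-product-likeness
from the RDKit Contrib scorers, sp³-carbon / aliphatic-ring / spiro-atom /
heavy-atom counts, molecular weight, and the ring count of the largest
atom-sharing fused ring system). KS distances are two-sample
Kolmogorov–Smirnov statistics × 100. Rediscovery and scaffold clustering
use Morgan fingerprints of radius 3 with 2048 bits and strict `> 0.6`
Tanimoto thresholds; clustering is single linkage realized as connected
components of the threshold graph, with acyclic molecules pooled into a
dedicated no-scaffold cluster.

## Synthetic fixtures

The corpus generator builds molecules constructively on a molecular graph
— random trees with valence bookkeeping, then optional ring closures —
and exports canonical SMILES, so validity holds by construction. It
follows organic-chemistry realism: a carbon-dominated alphabet (8:1:1:1:1:1
C:N:O:S:F:Cl), heteroatoms and halogens bond to carbon only, and ring
closures prefer 5- and 6-membered rings. What it deliberately does not
emulate: aromaticity, multiple bonds, stereochemistry, charges, and the
property distributions of real compound collections — so passing tests
demonstrate that the pipeline learns and measures SMILES syntax and
planted structure, not that it reproduces drug-like chemistry.
Planted-bioactivity sets graft a motif (default tetrahydrothiophene,
`C1CCSC1`, chosen to be expressible in the aliphatic corpus vocabulary)
onto random scaffolds for actives and verify by substructure search that
every active matches and no inactive does. The corruption utility
manufactures invalid strings of a requested error category (unmatched
parenthesis, dangling ring digit, an impossible `F=` double bond, or an
out-of-alphabet character) and verifies the classifier's label before
returning.

## Problem sizes and numerical choices

Desk-scale study conditions: pre-training on 3,000 synthetic molecules
(2 blocks, width 128, state size 32, batch 100, 60 cosine-scheduled epochs
at 5e-3, float32), 1,000-sample validity checks, fine-tuning on 36+4
planted actives with evaluation on 16 held-out actives plus 2,000
inactives, and a 10,000-permutation enrichment null. Full-scale settings
(4 blocks, width 256, N = 64, 100-token content) remain available through
the configs. Degenerate inputs are handled explicitly: empty corpora warn,
all-−∞ logits and empty KS samples raise, k beyond the ranked-list length
clamps with a warning, and fewer candidates than the selection cutoff
keeps everything.

A note on overfitting demonstrations: teacher-forced next-token accuracy
on a finite corpus is bounded by the prefix-ambiguity ceiling (the
majority-vote accuracy over identical prefixes; distinct strings force at
least one error per branch point). The memorization test therefore checks
that the trained model attains this ceiling — which it does to within
0.5% — and that greedy decoding replays a training string exactly.

## Limitations

Single-CPU NumPy training limits practical corpus sizes to tens of
thousands of short molecules; no GPU, mixed precision, data augmentation,
beam/nucleus sampling, or selective (input-dependent) state spaces; the
frozen-spectrum choice means the state dynamics are not adapted to
chemistry, only the readouts are; and synthetic fixtures cannot stand in
for ChEMBL- or COCONUT-scale chemical diversity.
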