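# Methods

This note records the model behind `medicrypt`, the parameter defaults
and why they were chosen, the numerical conventions, and what the test
suite does and does not establish.

## Chaotic maps

Four one-dimensional maps on the unit interval serve as primitives:

| map      | rule                                            | control        |
|----------|-------------------------------------------------|----------------|
| logistic | `T ← G·T·(1−T)`                                 | `G ∈ [3.58, 4]`|
| PWLCM    | `T/G`, `(T−G)/(0.5−G)`, or `F(1−T)` (3 branches)| `G ∈ (0, 0.5)` |
| LTS      | `(G·T·(1−T) + (4−G)·T/2) mod 1` (mirrored at ½) | `G ∈ (0, 4)`   |
| cubic    | `T ← λ·T·(1−T²)`                                | `λ = 2.59`     |

Interpretation choices for the LTS: the two branches are the `T < 0.5`
and `T ≥ 0.5` cases (they are mirror images under `T ↔ 1−T`), the tent
term is `(4−G)·T/2`, and the `mod 1` wraps the whole expression. The
LTS control interval is open at both ends because `G = 0` and `G = 4`
degenerate to a pure tent or pure logistic map.

**Sanitation.** Every step is clamped into `[ε, 1−ε]` with `ε = 2⁻³²`.
The maps all fix 0, and the logistic map sends `T = 0.5, G = 4` to
exactly 1 and thence to 0 — without the clamp a trajectory can die.
`ε` is ~10⁻¹⁰, four orders of magnitude below the 1/256 byte
quantization cell, so downstream statistics are unaffected.

## Keystream generator

The generator is a four-layer network (1 input neuron, two hidden
layers of `nhl`, 4 output neurons) whose neurons use chaotic maps as
transfer functions.

**Neuron semantics.** Pre-activation `a = (Σ w·x + b) mod 1`, then the
layer's map is applied `r` times with that neuron's own control
parameter. Keeping the mod-1 reduction before the map guarantees every
intermediate stays in the map's domain. The input neuron is
self-recurrent: its next input is its previous output, which is what
carries the trajectory from pass to pass.

**Initialization.** The key's second 32-bit half seeds the cubic map
(`(h + 0.5)/2³²`, so the seed is never exactly 0, which is absorbing);
after 50 warm-up iterations the trajectory fills `W0 (1×1)`,
`W1 (nhl×1)`, `W2 (nhl×nhl)`, `W3 (4×nhl)`, then `B0–B3`, then `P0–P3`
in row-major order. Values destined for `P` matrices are rescaled
affinely into the destination layer map's control interval. The first
key half seeds the input neuron's state.

**Layer→map assignment.** Default `(logistic, PWLCM, LTS, PWLCM)`.
The output layer must be PWLCM (or another measure-preserving map): the
logistic map's invariant density is arcsine-like and, for `G < 4`, its
attractor does not even cover (0, 1), so a logistic output layer
produces byte streams with support holes (measured entropy ~7.1–7.7
bits, χ² in the tens of thousands against a critical value of 310.5).
The PWLCM's slopes `1/G` and `1/(0.5−G)` sum in reciprocal to 1 over
each preimage set, so Lebesgue measure is invariant and the quantized
bytes are unbiased. Hidden layers may use any of the maps; the default
alternates so adjacent layers differ.

**Iteration feedback.** The `z` output sets the next pass's iteration
count, `r = r_min + floor(z · (r_max − r_min + 1))`, bounded in
`[r_min, r_max] = [4, 16]`. The lower bound matters: with `r ∈ [1, 16]`
about 12% of passes run only 1–2 chaotic iterations, too few to
decorrelate the output from the pre-activation's residual
non-uniformity (measured per-class χ² ≈ 900 for `r ≤ 2` versus ≈ 255,
the null mean, for `r ≥ 3`). Four iterations gives margin; the same
reasoning motivates the cubic map's 50-iteration warm-up.

**Quantization.** Byte streams are `min(floor(256u), 255)`; permutation
targets use `floor(u·K)` on the raw unit values, avoiding modulo bias.

**Defaults.** `nhl = 8` (wider layers slow generation linearly and
measurably add nothing at the byte level), `warmup = 50`, `r_max = 16`.

**Implementation.** Generation is a strictly sequential recurrence
(~10⁶ passes for a 1024² image), so the hot loop is compiled with
numba. A pure-Python reference (`forward_pass`) implements the same
arithmetic in the same operation order, and the test suite holds the
two paths bit-identical; a pure-Python fallback runs if numba is
unavailable. With the compiled path, a 1024×1024 encryption completes
in a few seconds on one CPU.

## Cipher

**P-box.** Source positions are taken in scan order and targets from
the keystream (`floor(u_t · N·M)`), applied as sequential swaps.
Realizing the permutation as a swap sequence (rather than a gather map
drawn from the stream) guarantees bijectivity for any stream content
and yields an exact inverse by replaying the swaps backwards.

**SP-box.** Substitution is a stateless XOR with stream `x`. The bit
permutation encodes the byte's four 2-bit groups as DNA bases under
rule `ky mod 8` of the 8 Watson–Crick-compatible codings, complements
each base, rotates the 4-base string left by `(ky >> 3) mod 4`, and
decodes under the same rule. Every variant is a
bijection on bytes with an exact inverse (verified exhaustively over
all 256×256×32 pixel/key combinations). One consequence worth
recording: because encode and decode use the same rule and both
complementation and rotation commute with the coding, the net bit
effect is rule-independent — complement the byte and rotate its 2-bit
groups. The rule index is retained for interface completeness and for
forward compatibility with mixed-rule variants, but it does not add
keyspace.

**Design consequences.** With a stateless substitution there is no
ciphertext chaining, so the cipher makes no plaintext-sensitivity
(NPCR/UACI-style) claims; the benefit is strictly local error
propagation, which is what the noise-attack analysis measures. The
per-pixel bit permutation was chosen over a global bit-plane reshuffle
because the per-pixel reading keeps the SP-box a byte-level bijection
with a trivially exact inverse.

**I/O.** Images are 8-bit grayscale; color inputs are converted by
luma. Lossless containers only (PNG, BMP, TIFF) — a lossy write would
destroy the ciphertext.

## Security metrics

* MSE / PSNR: `10·log10(255²/MSE)`; identical images report `inf`.
* Entropy: 256-bin histogram, `0·log 0 := 0`.
* Correlation: Pearson `r` over **all** adjacent pairs in a direction
  (horizontal is the headline; vertical and diagonal are also
  reported). Constant images return NaN.
* GLCM: quantization `floor(p·levels/256)` with `levels = 8`, one-pixel
  horizontal offset, unsymmetric, normalized. At 8 levels an ideal
  ciphertext has energy `1/64 ≈ 0.0156` and contrast
  `E[(i−j)²] = 10.5` for i.i.d. uniform levels — the right working
  point for judging ciphertexts; at 256 levels energy collapses to
  ~1.5·10⁻⁵ and ceases to discriminate.
* Execution time is reported but never asserted (hardware-dependent).

**Noise attack.** Salt-and-pepper corruption at density `d` hits each
ciphertext pixel independently (0 or 255, equal odds). Because
decryption maps each ciphertext pixel to exactly one plaintext pixel,
the damaged plaintext fraction equals `d` in expectation (minus the
~1/256 chance a grain reproduces the original byte) and recovery PSNR
stays above 15 dB at `d = 0.05` — the quantitative form of "the content
survives".

## Ensemble voting

Two-class aggregation over `K` models. Hard voting takes the modal
label; soft voting averages the class-A probabilities and reports
`100·mean(p)` against its complement, rounded to one decimal. Ties
break toward class A (the lexicographically smallest label); the rule
is arbitrary but documented and deterministic. Class-B's percentage is
computed as the complement of class-A's, which keeps the two summing to
100 under any input.

## Synthetic fixtures

`synth_xray` emulates exactly the properties of a chest radiograph that
the encryption benchmarks exercise: a smooth 8-bit intensity field
(Gaussian-filtered noise, correlation length ~min(N,M)/16), a bright
elliptical thorax with two darker lung fields, and mild sensor noise —
giving adjacent-pixel correlation ≥ 0.99 and a non-trivial histogram.
It does **not** reproduce radiographic texture, ribs, annotations or
detector artifacts, so green tests establish statistical cipher
properties, not clinical realism. The bundled 60-patient symptom table
(13 symptom codes in {0, 1, 2}; 30 Normal / 30 Pneumonia) ships
verbatim as CSV; its 13th column is unlabeled in the source layout and
is preserved as `unnamed`.

## Known limitations

* No cryptographic security proof and no NIST SP 800-22 battery; a χ²
  uniformity test and empirical entropy stand in.
* No chosen-plaintext resistance claims (stateless substitution).
* 8-bit grayscale only; no 16-bit, video, or DICOM metadata handling.
* The DNA rule index does not enlarge the keyspace (see SP-box above).
* Effective key entropy is 64 bits by construction; the generator is a
  keystream expander, not an entropy source.
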