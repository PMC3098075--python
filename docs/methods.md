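# Methods

## Problem and decision rule

Given a standard symptom vocabulary and a set of clinical symptom names,
each clinical name `s'` is scored against every standard name `s` with a
similarity function `Sim(s, s') ∈ [0, 1]` and assigned to the argmax when
the best score is `≥ τ`; otherwise it is left unassigned. Ties at the
maximum are broken uniformly at random. The gate is applied to the
maximum after the argmax, so `τ = 0` assigns everything, and the
threshold axis is shared by all metrics because every metric is
normalized to [0, 1].

Tie-breaking is reproducible by construction: clinical names are
processed in sorted order and each consumes exactly one draw from a
generator seeded by the run seed, whether or not it is gated and whether
or not there is a tie. This makes a name's tie-break independent of the
input row order, of the threshold, and — when its argmax is unique — of
the seed. (Consuming draws only on ties would let the stream shift as the
threshold moves names in and out of the assigned set, making recall
non-monotone in the threshold, which the sweep contract forbids.)

## Literal metrics

Comparison is per Unicode code point, no case folding or width
normalization; for Chinese symptom names one character is roughly one
morpheme, which is what makes character-level comparison meaningful.

* **Jaro.** `JD = (m/|s| + m/|s'| + (m−t)/m)/3`, `m` counted by the
  canonical windowed greedy matcher (window `max(⌊max(|s|,|s'|)/2⌋−1, 0)`;
  the floor at 0 keeps single-character identical pairs at score 1) and
  `t` = half the number of matched characters appearing out of order.
  `m = 0` gives 0. Note the formula is *not* monotone under losing a
  match: removing a crossed match raises `(m−t)/m` from 1/2 toward 1 and
  can outweigh the drop in the `m/|s|` terms, so "corrupting a character
  can only lower the score" holds only for transposition-free match sets;
  the test suite asserts exactly that restricted form.
* **Jaro-Winkler.** `JWD = JD + min(ℓ, cap)·p·(1−JD)` with common-prefix
  length `ℓ`, cap 3 and per-character weight `p = 0.1` (the cap is the
  "scale three" constant; the weight bound `p ≤ 1/cap` keeps scores ≤ 1).
  Both are configurable.
* **Smith-Waterman (linear gaps)** and **Gotoh (affine gaps)**. Standard
  local-alignment DP with cells floored at 0; affine gaps cost
  `open + (L−1)·extend`. Defaults: match +1, mismatch −2, linear gap −0.5,
  open −2, extend −0.5 — widely used string-similarity values; changing
  them shifts thresholds but not the method. Raw optima are divided by
  `match · min(|s|, |s'|)` (the score of perfectly aligning the shorter
  string) so both metrics share the [0, 1] threshold scale. With
  `open = extend = gap` the Gotoh recursion reduces exactly to the linear
  one, which the tests verify exhaustively on short strings.

## Remedy-based metrics

A symptom's *remedy bag* counts every remedy occurrence across its
prescriptions. Bags are keyed by (name, role) so that identical spellings
on the standard and clinical sides remain distinct entities.

* **Jaccard** on bag supports; two empty sets score 0.
* **TF-IDF cosine.** `w_ij = f_ij · log(N/df_j)` with `df_j` = number of
  bags containing remedy `j`. The numerator `N` defaults to the number of
  symptom bags (standard document-count semantics); `idf_base =
  "remedy_count"` instead uses the remedy-vocabulary size, in which case
  idf can go negative for very common remedies and is floored at 0 to
  preserve the non-negative-vector cosine contract. A remedy used by
  every symptom gets weight 0 — it carries no discriminative signal.
* **Bipartite SimRank.** Two symptoms are similar if their remedies are
  similar; two remedies are similar if they treat similar symptoms. Both
  tables start as identities and are updated jointly for a fixed `k = 4`
  iterations (a convergence tolerance is deliberately not the default;
  truncation is part of the method), reading only the previous iteration.
  Decay `C = 0.8`, a conventional choice, configurable. Neighborhoods are
  supports (presence, not frequency). Diagonals stay pinned at 1; a pair
  with an empty neighborhood scores 0. Off-diagonals are bounded by `C`
  and non-decreasing in `k` from this initialization. The implementation
  is the row-normalized bilinear form `C · P S P'` in numpy and is tested
  elementwise (1e−12) against a literal double-loop transcription of the
  update formulas.

Empty or missing bags score 0 against everything rather than raising:
clinical corpora do contain such records and normalization should degrade
gracefully.

## Hybrid metric and evaluation

`Sim = α·Sim_L + β·Sim_RB` with `α + β = 1` enforced — the weight grid is
one-dimensional, and the convex combination keeps scores in [0, 1]. The
endpoints `α ∈ {0, 1}` reproduce the single-family pipelines bit-for-bit
(checked as exact DataFrame equality, not approximate).

Precision is `|CNS|/|NS|`, recall `|CNS|/|CSN|`, F-Measure the balanced
harmonic mean (F1). Clinical names whose gold target is the NONE sentinel
are still scored and may be wrongly assigned — they count toward `|NS|`
but never `|CNS|`, and are excluded from `|CSN|`. Degenerate conventions:
`P = R = F = 0` when nothing is normalized or when `P + R = 0`.

## Synthetic corpus generator

The generator emulates, at about one-tenth scale, the structure of a
standard prescription dataset paired with a clinical-records dataset:

| parameter | default | meaning |
|---|---|---|
| `n_standard` | 60 | standard vocabulary size |
| `n_remedies` | 150 | remedy vocabulary size |
| `p_bodypart` | 0.67 | standard name contains a body-part token |
| `p_prefix_std` / `p_prefix_clin` | 0.99 / 0.80 | body part is the prefix, given present |
| `p_multi_synonym` | 0.78 | standard has ≥ 2 clinical variants |
| `p_unnormalizable` | 0.10 | clinical names with no standard meaning |
| `signature_size_mean` | 6 | Poisson mean of remedies per signature (min 2) |
| `remedy_dropout` | 0.2 | per-prescription omission of a signature remedy |
| `noise_remedy_rate` | 0.5 | Poisson rate of spurious remedies per prescription |
| `char_edit_rate` | 0.05 | per-character corruption in variants |
| `n_prescriptions_per_name` | 5 | prescriptions sampled per name |
| `n_alternative_pairs` | 10 | interchangeable remedy pairs |

Names concatenate 1–2-character tokens from three disjoint inventories
(body part, disease property, degree) drawn from a reserved CJK codepoint
block, so the literal metrics operate on single-character morphemes as
they would on Chinese; an ASCII-ish mode exists for debugging. Degree
tokens appear with probability 0.5. Clinical variants apply synonym
substitution (p 0.5, from a fixed synonym table), prefix relocation with
probability `1 − p_prefix_clin/p_prefix_std` (so the clinical prefix rate
lands on its target), degree deletion (p 0.3) and character noise.
Multi-synonym standards receive 2 variants (3 with p 0.3). The
unmappable count is set deterministically to
`round(n_variants · p/(1−p))`; those names are junk token strings with
arbitrary remedy draws. Members of an alternative pair are dispensed
interchangeably (probability 1/2 each) wherever a signature calls for
one, giving the two remedies exchangeable co-occurrence laws — a signal
visible to SimRank but not to set/cosine comparison. Generation is fully
deterministic given the seed; identical configs produce byte-identical
TSV output.

**What the generator does not model:** real Chinese lexical semantics,
dose/preparation fields, patient-level longitudinal structure, and —
importantly — the noisiness of real clinical remedy records. Synthetic
remedy bags are cleaner than real ones, so remedy-based metrics score
near-ceiling here, whereas on real data the literal metrics tend to carry
more of the weight. Passing tests therefore demonstrate correctness of
the machinery and the *relative* structural claims (hybrid ≥ best single
family; prefix boost helps; SimRank sees alternative remedies), not
absolute real-data accuracy levels.

## Problem sizes and numerical choices

Default experiment size is 60 standards / ~135 clinical names / 150
remedies, which keeps the quadratic SimRank tables and the full
grid-search (4 literal × 3 remedy metrics × 11 weights × 10 thresholds)
comfortable on a laptop; all sizes scale via `GeneratorConfig`.
Alignment scores are exact floats (no tolerance tricks); oracle
comparisons use 1e−9 (alignment) and 1e−12 (SimRank). Cosines are clamped
at 1 to absorb ulp-level overshoot in self-similarity. Score ties in the
argmax are exact float equality — coarser score quantization produces
more ties, which the seeded tie-break resolves reproducibly.

## Known limitations

* Word segmentation, ontology/semantic similarity and multi-label
  assignment are out of scope: one standard name per clinical name,
  character-level comparison only.
* SimRank is computed densely; corpora beyond a few thousand symptom
  names would need a sparse or approximate variant.
* The gold mapping is assumed consistent (one target per clinical name);
  conflicting expert annotations are rejected, not adjudicated.
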