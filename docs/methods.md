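# Methods

## Problem

Calpains are Ca²⁺-activated cysteine proteases. The large subunit always
carries the catalytic domain DII with a Cys/His/Asn catalytic triad;
*typical* calpains additionally carry a C-terminal domain DIV containing a
penta-EF-hand (PEF) — five consecutive ~29-residue helix-loop-helix EF-hand
motifs, the fifth of which mediates heterodimerization with the small
subunit CAPNS1. Generic single-motif EF-hand models (the PROSITE/Pfam
style) tend to merge adjacent motifs and systematically undercount, so PEF
domains are missed. Two questions drive this toolkit:

1. **How many EF-hand motifs does a protein carry, and do five of them form
   a PEF domain?** Answered with five *position-specific* profile HMMs, one
   per EF-hand slot (EF-1…EF-5) of the PEF domain.
2. **Is the catalytic triad intact?** Proteins carrying DII but missing at
   least one triad residue are *calpain-like inactive* (pseudo-enzyme)
   candidates.

Combining the two axes with DII detection yields a four-way architecture
label: typical-calpain, atypical-calpain, calpain-like-inactive,
not-calpain.

## Profile HMM

The model is the classic match/insert/delete profile (Krogh/Durbin; the
core of HMMER's Plan7 without the flanking N/C/J states). Match states
1..L carry position-specific emissions; inserts emit the background;
deletes are silent. Transition groups per node are M→{M,I,D}, I→{M,I},
D→{M,D}, with Begin acting as M₀ and the node-L *→M entries acting as
exits to End.

**Construction** (`build_profile`): match columns are assigned by the
standard gap-fraction heuristic (match iff gap fraction < 0.5). Emission
estimates are counts plus a background-proportional pseudocount,

  e_k(a) = (c_k(a) + w·q(a)) / (Σ_b c_k(b) + w),

with weight w = 1 by default (w → 0 gives the empirical frequencies
exactly). Transition counts come from each row's implied state path; their
pseudocount is a Dirichlet prior with the classic Plan7 shape
(m→m 0.794, m→i 0.028, m→d 0.013, i→m 0.155, i→i 0.133, d→m 0.900,
d→d 0.563), scaled by the same w. A uniform-over-legal-moves prior is
available (`transition_prior="uniform"`) but is not the default: on a
small ungapped seed it puts ~3% insert and ~3% delete probability on every
node — an order of magnitude above what real family builds produce — which
both fattens the low tail of scores of sequences sampled from the model
and misstates indel propensities. Sequence weighting (Henikoff etc.) and
Dirichlet emission mixtures are out of scope for v1.

**Motif seeds from a master alignment** (`slice_alignment`): motif
coordinates are given 1-based inclusive on the *ungapped* reference row;
the slice takes every alignment column between and including the columns
of the two boundary residues, so insert columns internal to the motif are
kept. Rows all-gap within the slice are retained and flagged
(`metadata["all_gap_ids"]`), never silently dropped. Real reference
coordinates (e.g. the EF-hand coordinates of human CAPN1) are input data —
the package never invents them; shipped fixtures are synthetic.

## Scoring and statistics

All dynamic programming runs in natural-log space with log-sum-exp;
scores are log-odds against the background (uniform 1/20 by default) and
are reported in bits. Ambiguity residues (X/B/Z/U/O) score as the
background (log-odds 0). Two modes:

* **global** — Begin-to-End over the whole query;
* **local** — entry into any match state with uniform mass 1/L, free exit
  after any match state, unmatched flanks scored as background. Local mode
  is what scanning uses.

Viterbi tie-breaks prefer Match over Delete over Insert, then the smaller
node index, making traced paths deterministic. `forward ≥ viterbi` holds
by construction (sum over paths vs best path) and is regression-tested on
1000 random model/sequence pairs; both DPs are validated to 1e-9 against
brute-force path enumeration on small models.

**E-values** (`calibrate`): local Viterbi bit scores of i.i.d. background
sequences (fixed length 400) are fitted with a Gumbel law by maximum
likelihood; P(S > s) = 1 − exp(−exp(−λ(s − μ))) and E = n_targets · P.
The default calibration sample is 4000 sequences: the ML parameter error
scales as 1/√n, and at n = 1000 it is comparable to the extreme-value
approximation error itself, whereas at 4000 it is negligible while
calibration still takes about a second per model. The n_targets
convention is per-run: `scan` defaults to 1 (per-sequence E-values), the
batch counter uses the number of queries in the run (per-database,
HMMER-style); both are explicit parameters because a bare "E ≤ 0.01"
cutoff is otherwise ambiguous.

**Hit extraction** (`scan`): iterated best-hit with masking — find the
best local Viterbi hit; if its E-value passes the cutoff, record it, mask
its query span (masked residues become unmatchable), repeat. Returned
hits are therefore non-overlapping by construction.

## EF-hand counting and PEF calling

`count_ef_hands` scans the five motif models independently and reduces
the union of passing hits to a non-overlapping set by greedy selection on
ascending E-value (ties: higher bits, then leftmost). A query region can
therefore satisfy at most one motif model — the guard against the
double/under-counting failure mode of pooled single-motif models. The
EF-hand count is the size of that set, and relaxing the cutoff can never
decrease it.

`call_pef` calls a PEF domain when some consecutive run of ≥5 accepted
hits spans at most 400 residues (the scale of a complete PEF domain plus
linkers) and, by default, has non-decreasing motif indices along the query
(the conserved EF-1→EF-5 arrangement). Both knobs — window and ordering —
are exposed and recorded; with ordering off, any ≥5 EF-hand hits in the
window qualify. The count rule does not require the five hits to come
from five *distinct* models; the ordering requirement makes that the
overwhelmingly common case while tolerating a duplicated slot.

## Catalytic-triad screen

`map_reference_positions` maps 1-based ungapped reference positions to
alignment columns; `screen_triad` reads those columns for every row.
Matching is strict: only the exact required letter counts, and a gap,
ambiguity code or conservative substitution marks the residue missing —
the screen asks about catalytic competence, and a conservative call never
labels an uncertain protein "intact". The per-query alternative (no
master MSA) reads the triad through the DII hit's Viterbi path in the
classifier; a triad node deleted from the path or outside the matched
node range yields status *unknown*, because absence of alignment evidence
is not evidence of residue loss.

`filter_redundant` reproduces the fragment/splice-variant filter applied
before family-wide screens: exact substrings of a longer kept sequence
are removed as fragments; pairs with identity ≥ 0.97 over the shorter
sequence keep the longest member (ties: lexicographically smaller id).
Identity is match-count over an optimal pairwise alignment, or aligned-row
identity when an MSA is supplied. The filter is idempotent and every
removal carries a machine-readable reason.

## Architecture classification

Label assignment is a pure function of (catalytic-domain hit, triad
status, PEF):

| DII hit | triad    | PEF | label                 |
|---------|----------|-----|-----------------------|
| no      | any      | any | not-calpain           |
| yes     | missing  | any | calpain-like-inactive |
| yes     | intact   | yes | typical-calpain       |
| yes     | intact   | no  | atypical-calpain      |
| yes     | unknown  | any | atypical-calpain (warning) |

A demonstrably broken triad outranks a PEF (the pseudo-enzyme case, cf.
CAPN6); an unknown triad is never grounds for an inactive call. The PEF
search covers the whole sequence by default since domain order varies
across families; `downstream_only` restricts it to after the DII hit.

## Synthetic study conditions

Everything is testable offline because the generators in
`synthetic_fixtures` emulate the real inputs with exact ground truth:

* **Seed alignments**: 29 columns × 10 rows (the size of a ten-protein
  training family). Six anchor columns at the canonical calcium-
  coordinating loop positions (10, 12, 14, 16, 18, 21 — loop residues
  1, 3, 5, 7, 9, 12) are 92% conserved; every other column's emission
  profile is a Dirichlet(0.25) draw, so conservation varies per column as
  in real families. This matters statistically, not just cosmetically: an
  early design with uniformly conserved columns produced a *multimodal*
  null score distribution (best null hits come in discrete ~3.5-bit
  consensus-match jumps) that no Gumbel law fits; position-specific
  profiles give a dense score landscape and textbook extreme-value
  behaviour.
* **Motif planting** samples instances from the model itself (honest
  variability, including indels), not the consensus; spacers and flanks
  are background runs (spacers 10–40, flanks 50–150 residues). Truth
  tables record exact spans, so expected counts are computable without
  re-running the generator.
* **Triad families**: 120-column consensus with triad letters at
  (30, 60, 90); members mutate at 5% per non-triad column with 2% gaps; a
  chosen fraction receive disabling substitutions at 1–3 triad columns
  (which ones is recorded).
* **DII stand-in**: a 90-node profile (scaled down from the ~300-residue
  domain to keep scans fast) with perfectly conserved C/H/N triad nodes at
  (25, 50, 75).

What the fixtures do **not** emulate: real amino-acid composition
(background is uniform 1/20), phylogenetic correlation between family
members, motif-motif sequence similarity (real EF-1..EF-5 are homologous
to each other; the synthetic panel's five models are independent, which
makes per-slot assignment *easier* than in real proteins), and alignment
error from the upstream aligner. Passing the planted-truth suites
therefore demonstrates correctness of the machinery and calibration, not
field performance on real proteomes.

## Numerical and degenerate-input choices

* Probabilistic invariants (emission rows and transition groups sum to 1
  within 1e-9) are asserted on every model construction.
* Model text serialization stores negative natural logs at 5 decimals
  (HMMER3 style, `*` = zero); readers renormalize to repair rounding.
* Gumbel P-values use expm1 for numerical stability; degenerate
  calibrations (all null scores equal) raise instead of fitting.
* An all-delete sample path would emit the empty string; `sample_sequence`
  falls back to the node-1 consensus letter so a ProteinSequence is always
  valid.
* Masked scan positions are excluded from emission, so iterated hits can
  never overlap; a query of only masked/ambiguous residues yields no hits.

## Problem sizes

The shipped validation runs use 480 brute-force oracle pairs, 1000
forward-vs-Viterbi pairs, 4000-sample calibrations checked on 2000 fresh
nulls, 200 planted-count fixtures (counts uniform on 0–5), a 50-sequence
triad family with 7 knockouts, and four architecture fixtures. The full
test suite runs in under a minute on one CPU; `scripts/acceptance.py`
takes about 40 seconds.
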