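# Methods

## The consensus model

A leucine-rich-repeat unit is detected through its highly conserved
segment (HCS), an 11- or 12-residue window with five anchor positions
(window-local 1-based): 1, 4, 6, 9 and the final position.  Positions
4 and 6 are internal L anchors; position 9 takes the N class
(Asn/Thr/Ser/Cys) in the 11-mer and the C class (Cys/Ser/Asn) in the
12-mer; positions 1 and last are terminal anchors; all other positions
are unconstrained.  A window matches when every anchor residue belongs
to its class; the matcher returns a per-anchor evidence trail naming
the class cited and the relaxation used (`none`, `hydrophobic_ext`,
`terminal`), so a report can distinguish a canonical hit from one that
leans on the permissive rules.

Class membership is configuration, not code (`ResidueClassConfig`):

| knob | default | rationale |
|---|---|---|
| `l_core` | L, I, V, F | the canonical L class |
| `l_hydrophobic_ext` | L, I, V, F, M, Y, W, A, C, G | internal anchors tolerate any hydrophobic residue; G is included because the published Panx1CT segments require Y, M and G at internal anchors — its presence is the minimal extension reproducing that table and is an explicit knob, not a hydrophobicity claim |
| `n_class` / `c_class` | N, T, S, C / C, S, N | position-9 classes of the two variants |
| `internal_anchor_policy` | `hydrophobic` | `core_only` available for strict scans |
| `terminal_policy` | `any` | "relatively hydrophilic" terminals are not a defined set; since the union of the hydrophobic class and any plausible hydrophilic set covers essentially the whole alphabet, `any` is the honest default.  `hydrophilic_set` (L class ∪ a configurable hydrophilic set) and `strict` (L class only) support sharper scans |

`X` is accepted in input but satisfies no class.  Enlarging any class
set can only add matches (a tested monotonicity invariant).

An 11- and 12-mer hit at the same start are one `HcsMatch` with both
variants, mirroring the "X or Y" presentation of published segment
tables; hits at different starts are never merged, and overlapping
hits are all reported.  Note the source literature names the
ScanProsite-derived HCS both as a 14-residue span (S328-L341) and as
the 12-mer L329-E340; the scanner reports match-window coordinates
(the L329 style) and surfaces the discrepancy rather than resolving
it — deletion-construct building uses whatever span the user passes.

## Motifs, domains, null model

Each HCS gains a putative variable segment (VS) from its end + 1 for
up to `vs_max_len` residues (default 7, the length of the one
experimentally delineated VS, K342-K348), truncated at the next hit's
start − 1 and at the sequence end.  Hits whose consecutive starts are
≤ `adjacency_max` apart (default 30, a typical LRR unit length; the
published Panx1CT chain has a maximum gap of 24) chain by single
linkage into putative LRR domains; a domain needs ≥ 2 members.

For an i.i.d. background with residue frequencies f, anchor positions
are independent, so the per-start match probabilities are products of
class probabilities: p11 = P(term)·P(int)²·P(N)·P(term), analogously
p12 with the C class.  The expected number of merged hit starts in a
length-n sequence is (n−10)·p11 + (n−11)·(p12 − p_both) with p_both
the probability both windows match at one start (shared anchors 1, 4,
6; position 9 in the class intersection; both terminals).  Under the
defaults the C class is a subset of the N class and terminals accept
anything, so p_both = p12 and the 12-mer term vanishes — random-window
Monte Carlo and per-sequence hit counts confirm the closed form in the
test suite.  No multiple-testing correction is applied to scan hits;
the null model is reported for calibration only.

## Conservation and annotation overlap

Conservation is tested on a user-supplied alignment (computing
alignments is out of scope).  Each row carries a bijection between its
ungapped 1-based residue positions and alignment columns; a hit's
window is mapped through columns into every other row and re-tested
with the same matcher in the ortholog's own residues — the claim being
checked is that the ortholog *sequence* fits the consensus, not that
columns are identical.  A mapping interrupted by gaps is reported
non-conserved with reason `gap`; a span facing only gaps is
"unmappable", a result rather than an exception.  A row conserves a
hit when at least one of its variants re-matches, consistent with the
scanner accepting either variant.

Annotation overlap uses closed intervals: one shared residue is an
overlap, adjacency is not (the published caspase-site overlap,
hit 376-387 vs site 375-378, is a 3-residue partial overlap).  The
packaged `table1_annotations.tsv` reproduces the published sites of
interest so the overlap report runs offline.

## Assay computations

**Colocalization.**  The evaluation mask is explicit because
acquisition software does not publish its masking: `union` of the
per-channel above-threshold masks (default), `intersection`, or
`whole_image`, always recorded in output.  Pearson's r is the sample
correlation over the mask; with fewer than two mask pixels or zero
variance in a channel it is *undefined* and reported as such, never
as 0.  Colocalization rate = 100 · (pixels above threshold in both
channels) / (foreground pixels).

**Densitometry.**  Per-band signal is the sum of baseline-subtracted
intensity (clipped at 0) inside the band's declared window; the lane
total sums the declared windows only, so non-specific regions never
contribute.  Baseline is `none` by default; `rolling_min` subtracts a
rolling-minimum pedestal (window in sample points).  An all-signal
sensitivity mode is deliberately absent from the default path — the
declared-windows rule *is* the quantification definition.

**Growth.**  Two-point doubling time is DT = Δt·ln2/ln(N_later/N_earlier).
The literature sometimes prints the count ratio in the opposite order,
which makes DT negative for growing cultures; this implementation
fixes the operand order so growth gives positive DT and reports
non-increasing windows as undefined with a reason.  Regression mode
fits ln N against t over ≥ 3 points and returns ln2/slope, the
preferred estimator for noisy series.  Dead fraction is
100·dead/(live+dead) per time point (NaN when the total is 0); MTT
normalization is 100·OD/mean(control ODs).

## Synthetic data: what it emulates, what it does not

Every generator takes one seed, uses a private `numpy` Generator (no
global state), and emits a `SyntheticTruth` sufficient to predict the
expected analysis result without rerunning the generator.

* `gen_sequence` — i.i.d. background from given frequencies with
  planted consensus windows; `canonical` plants are the deterministic
  core-class instantiation (`LGGLGLGGNGL` / `LGGLGLGGCGGL`),
  `relaxed` plants sample anchors from the extended classes.  Real
  proteins are not i.i.d.; the generator calibrates the scanner and
  null model, not compositional realism.
* `gen_ortholog_set` — point substitutions per row at a given rate;
  `conservative` mode never touches protected (planted-anchor)
  positions, so planted motifs are conserved by construction.  No
  indels are generated; gap handling is exercised with scripted
  alignments.
* `gen_channel_pair` — a membrane ring with Gaussian radial
  cross-section (a point-spread-blurred membrane in a confocal
  section) versus either the identical ring or an interior Gaussian
  disc whose above-threshold mask is disjoint from the ring's;
  additive Gaussian noise clipped at 0.  No attempt at a realistic
  microscope PSF, z-stacks or segmentation — the generator supports
  metric-ordering and identity tests only.
* `gen_growth` — total cells n0·2^(t/dt)·exp(ε), ε ~ N(0, σ)
  (multiplicative log-normal noise, matching the log-linear fitting
  model); dead cells are a binomial draw of the total at the dead
  rate and live = total − dead, so the expected dead fraction equals
  the rate and the live curve keeps the true doubling time.  Defaults
  (n0 = 1e5, counts every 24 h for five points) mirror a standard
  5-day Trypan-blue proliferation protocol.
* `gen_lane` — fraction-weighted Gaussian bands plus noise scaled by
  the tallest peak, clipped at 0; quantification windows at ±3 peak
  widths.  Defaults emulate a three-band oligomer lane (fractions
  0.5/0.3/0.2).

Passing recovery tests on these generators shows the estimators are
correct under their stated models; it does not validate thresholds or
windows against real microscope or blot data, which are user inputs.

## Numerical and design choices

* Coordinates: 1-based, inclusive, stated in every report header.
* Suffix deletions use an `END` sentinel; deletion products carry a
  position map from original to product coordinates so annotations
  lift over (deleting 299..END of a 426-mer leaves last position 298).
* FASTA output wraps at 60 columns (cosmetic convention; round-trips
  byte-identically).
* FASTA input is validated line-by-line before parsing so alphabet and
  header errors name the offending line; parsing itself is Biopython.
* Degenerate spans: a scan region shorter than 11 residues returns an
  empty result with a logged warning; an empty band window quantifies
  to 0 with a warning; a zero-count or non-increasing growth window
  yields an undefined doubling time with a reason, never an exception.
* Determinism: scanning is a pure function of (sequence, config);
  reports embed the fully resolved config, input digests and package
  version.

## Test problem sizes

The suite exercises the scanner against an independent brute-force
window oracle on 1,000 random length-200 sequences, checks null-model
calibration on 1e5 random 11-mer windows and on 150 plant-free
length-200 backgrounds (3-standard-error agreement), and runs
parameter-recovery checks at the generator defaults (5-point growth
series, three-band lanes, 128×128 images).  These sizes keep the whole
suite under ~10 s while leaving the statistical checks well-powered.

## Known limitations

* The matcher reproduces the published degenerate-consensus criteria;
  it is not a PROSITE generalized-profile search and assigns no
  scores or E-values.
* The default `terminal_policy="any"` is deliberately permissive; on
  random backgrounds it yields ~0.05 hits per start, so scan reports
  should always be read against the attached null model.
* Conservation requires an alignment whose row offsets place each
  ortholog in its own full-protein numbering; offsets default to 1.
* The assay layer consumes extracted profiles and matrices; image
  segmentation and blot-to-profile extraction are out of scope.
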