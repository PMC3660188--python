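# Methods

This note documents the models and conventions behind each stage, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the known limitations.

## Coordinates and sequences

All coordinates are 1-based and inclusive at both ends, on the forward
strand — the convention of primer "location" tables in this field.
Reverse-strand regions are returned as the reverse complement of the
forward-strand slice. Sequences are uppercase IUPAC DNA; `U` is
rejected (DNA only), lowercase input is folded. FASTA output wraps at
60 columns so that files are deterministic byte-for-byte.

## Pentamer spectra

A DYZ1 HaeIII unit is modelled as a tiling of 5-base units, each
classified by Hamming distance *d* to the reference motif `TTCCA`
(*d* ∈ 0…5; exactly 15 motifs have *d* = 1). A spectrum holds per-motif
counts, the aggregate count per distance class, and the residue (bases
not assigned to any pentamer); the invariant
`5 × Σcounts + residue = length` is enforced at construction.

The published per-unit counts do not state the segmentation rule, and
they leave 14/19/15 bases unassigned in the three 3564/3564/3465-base
units — so some re-anchoring rule beyond naive frame-1 tiling was
clearly in play. Two rules are provided:

- **fixed-frame**: tile from position 1 in steps of 5; the trailing
  `L mod 5` bases are residue. Transparent but fragile: one indel
  shifts every downstream tile.
- **dynamic** (default): minimise
  `Σ(tile distances) + skip_penalty × (unassigned bases)` by dynamic
  programming. The default `skip_penalty = 3` means a tile of distance
  ≤ 2 is always preferred over skipping its five bases, while a short
  skip is cheaper than reading several heavily mutated tiles across an
  indel-induced phase shift — this reproduces "in-frame" behaviour on
  clean arrays and re-anchors across indels. Cost ties resolve to the
  segmentation whose first differing decision assigns a pentamer rather
  than a skip (leftmost assignment), which makes the output unique.

Exact reproduction of every published per-motif cell would require the
original (unstated) rule and the original unit sequences; the shipped
published-count table is used for internal-consistency checks (the
fifteen *d* = 1 motif counts sum to the printed aggregates 292/289/282)
rather than as a segmentation oracle.

Arrays must be unambiguous; ambiguity codes are rejected because a
Hamming distance to an ambiguous base is ill-defined and satellite unit
sequences are concrete.

## Virtual digestion

Recognition patterns are IUPAC-expanded into regular expressions with a
lookahead so that **overlapping occurrences all count**. Published
"frequency of cut sites" tables rarely state a strand policy, so this
one is explicit and configurable (`--strand forward|both`): palindromic
sites (IUPAC-aware reverse complement equals the pattern) count once
per double-stranded site; non-palindromic patterns are additionally
sought on the reverse strand and reported at their forward-strand
coordinate. "Site length" follows the informative-base convention:
the count of non-N letters in the pattern.

Cut geometry: `cut_top`/`cut_bottom` are offsets in bases from the 5'
end of the recognition sequence (on the strand carrying it) to the cut.
For a reverse-strand hit the bottom offset, mirrored about the site
end, gives the top-strand cut. Type IIS enzymes (Eco57I, FokI, …) cut
outside their recognition site; in the shipped panel their offsets are
left empty, which disables fragmentation but not counting, and a cut
that falls outside the molecule is ignored for fragmentation while the
recognition hit still counts. Fragment sets always conserve length
(`Σfragments = sequence length`; linear topology only — circular
digestion is out of scope). PCR-RFLP calls are `uncut` (single
full-length fragment) or `cut` (the fragment pattern), the gel
end-point analogue.

The bundled 65-enzyme panel and the published frequency counts for
AC068123.5/DU145/LNCaP are editable TSV assets. Two published
observations are retained as data, not resolved in code: Eco57MI
changes 1→2 in both cell lines yet only Eco57I is described as
"gained" (presence/absence transitions and count changes are reported
separately as `lost`/`gained` vs `changed`); and two rows of the
published RFLP assay table have fragment patterns that do not sum to
the stated product size (GOLY-SNV_1: 289+282 ≠ 531; DAZ-SNV_IV:
398+262 ≠ 630) — the consistency test asserts exactly this set.

## Variant tallies

Global alignment is Needleman–Wunsch with affine gaps, maximised over
three layers. A gap of length *k* costs `open + (k−1)·extend`; defaults
are match +1, mismatch −1, open −5, extend −1. The open≫extend ratio is
deliberate: multi-base indels stay as single gap runs instead of
scattering, which is what event tallying needs. The original study's
aligner parameters are unstated, so the scores are overridable, and an
existing alignment can be ingested (CLUSTAL or aligned FASTA) —
ingestion is the authoritative route for reproducing published counts,
since a recomputed optimal alignment of near-perfect tandem repeats can
legitimately place an equivalent-cost gap run a few units away.

Traceback is deterministic: at equal score the diagonal move wins, then
a gap in the second sequence, then a gap in the first. The DP is
implemented with per-row numpy vectorisation (the within-row affine
scan uses a running-maximum prefix trick), float32 matrices, and is
checked in the tests against an exhaustive enumeration of all
alignments (length ≤ 6) and against an independent aligner's optimal
score on longer sequences.

Tallying treats the first sequence as the reference: substitutions are
columns with two differing bases (a gapped column is never a
substitution); one maximal gap run is one indel event located on
reference coordinates (deletion: first deleted base; insertion: the
base left of the insertion point); net length change is the signed sum
of event lengths and always equals `len(b) − len(a)`.

## STS deletion mapping

In-silico PCR is strict by default: the forward primer must match the
forward strand exactly and the reverse primer's reverse complement must
occur downstream; the smallest product is reported (end-point PCR
favours short products). Mismatch tolerance is opt-in. Amplicon length
from coordinate tables is `rev.end − fwd.start + 1`.

A profile covers every marker of its panel exactly once. A deletion
class is called iff all its `absent` markers are absent **and** all its
`flanks` are present; nested/overlapping matches are all reported (no
masking) and sorted by name, with flank requirements available to
disambiguate. The shipped signature config is a curated approximation
of the classical deletion intervals (AZFa, P5/proximal-P1, P5/distal-P1,
AZFc/b2-b4, gr/gr, b2/b3, b1/b2, TSPY–TSPY) mapped onto the bundled
51-marker panel; the exact per-study marker membership of these classes
exists only graphically in the literature this panel reflects, so the
engine is signature-agnostic and the config is data, clearly labelled
as curated. PCR annealing/extension conditions ship as inert metadata.

Of the published coordinate tables, every primer-combination product
size is reproduced by the coordinate arithmetic except the three
combinations using primer "SAS 12", which are consistent only with a 3'
location of 3571 rather than the printed 3606 (all three differ by
exactly 35), and the combinations using "SAS 1", which binds upstream
of the unit start (negative coordinates). These are recorded in the
primer asset's `note` column; the consistency checks cover the
self-consistent rows.

## qPCR absolute quantification

The model is `Ct = intercept + slope·log₁₀(copies)` under constant
amplification efficiency, fitted by ordinary least squares of Ct on
log₁₀(copies) — the regression direction that makes a ten-fold series
at 100% efficiency give slope `−1/log₁₀2 = −3.3219…` (printed −3.32).
Replicates enter as individual points, not means. Efficiency is
`10^(−1/slope) − 1`; note that a slope of exactly −3.32 corresponds to
an efficiency of 1.0008, not 1.002. A fitted curve carries warnings
when R² < 0.99 or the slope leaves [−3.6, −3.1] (≈ 90–110%
efficiency). Unknowns are quantified by inverting the line
(`copies = 10^((Ct−intercept)/slope)`), and copy counts normalise as
`copies × 3.3 pg / input mass` — 3.3 pg being one haploid human genome
equivalent (configurable). Input mass is taken as given; Ct values are
inputs (no fluorescence-trace baselining, no melt analysis, no ΔΔCt).

Published cell-line copy numbers (such as 742 and 1945 copies per
3.3 pg) require the study's unpublished Ct measurements; the toolkit
reproduces the quantification machinery, and its tests substitute
property guarantees: exact fit/quantify round trips on noise-free
series, and seeded recovery (median slope error < 0.03 over 200
simulated curves at efficiency 0.9–1.1 with Ct noise sd 0.1; unknowns
quantified from noise-free Ct against the noisy fitted curve stay
within 10% of truth in the median).

## Synthetic data — what it emulates, and what it does not

All generators are pure functions of (spec, seed) via
`numpy.random.default_rng`, and every generator returns its ground
truth so recovery tests need no external data.

- **Arrays**: 712 units (3,560 bases — the scale of a 3,564-base
  HaeIII unit) with per-unit derivative probabilities mirroring the
  published reference composition (292/142/37/9/1 of 710 units at
  *d* = 1…5). Derivative positions and substituted bases are uniform,
  so truth spectra are exact by construction. Real units have
  non-uniform motif usage (e.g. TTCGA is far commoner than TACCA among
  *d* = 1 derivatives) and positional structure along the array;
  passing spectrum-recovery tests therefore shows the tiling and
  bookkeeping are correct, not that the generator is a sequence model
  of real DYZ1.
- **Variants**: explicit indel events plus randomly placed
  substitutions, all separated by ≥ 20 bases so an optimal realignment
  can recover them unambiguously. Real mutation processes cluster;
  the spacing is a deliberate identifiability condition, and the
  recovery tests assert exact substitution counts and indel lengths
  (indel *positions* may shift by whole repeat units between
  equal-cost alignments of tandem repeats).
- **Dilution series**: `Ct = Ct₁ − log(copies)/log(1+E) + N(0, σ)` with
  Gaussian cycle-scale noise (a standard qPCR assumption; the
  triplicate structure is emulated, pipetting error in the dilution
  steps themselves is not). Defaults: 2×10⁸ copies down in ten-fold
  steps over 6 levels, triplicates, E = 1.0, Ct₁ = 40.
- **STS datasets**: a planted class yields a profile absent exactly at
  the class's markers; the optional mock template concatenates
  synthetic primer-flanked loci for present markers (random 20-mer
  primers, 100-base inserts, 60-base linkers). It is a mock for
  exercising the in-silico PCR path, not a model of MSY architecture.

The cell-line comparison tests use clearly-labelled synthetic
stand-ins: the real unit sequences and their published alignment are
not redistributable with this package, so the tests plant exactly the
reported events (23 or 27 substitutions; +16/−1/−15 or +15/−114 bp
indels; ablation of the six/eight named recognition sites plus one
created Eco57I site) and verify the pipeline recovers the reported
numbers through its real code paths. The digest stand-in compares a
nine-enzyme sub-panel chosen so the planted sites are the only signal.

## Numerical and policy choices

- Alignment DP uses float32 (scores here are small integers, exact in
  float32); traceback comparisons carry a 10⁻³ tolerance so
  non-integer custom scores cannot derail layer selection.
- Segmentation DP is integer-cost; the exhaustive tiling oracle in the
  tests covers all sequences up to 30 bases.
- Standard-curve fitting requires ≥ 3 distinct copy levels and nonzero
  variance; degenerate inputs raise rather than warn.
- Duplicate enzyme names, mismatched panels, markers outside a panel,
  and signatures referencing unknown markers are all hard errors.
- Problem sizes in the default test run (30 full-size alignment
  recovery pairs, 200 simulated standard curves, 60-example oracles)
  were chosen to exercise the full-scale study conditions while keeping
  the suite fast; they are the package's own choice of test scale.

## Known limitations

- No generic tandem-repeat discovery: the reference motif is fixed
  (configurable as a single motif), not inferred.
- No true multiple alignment; three-way comparisons are pairwise.
- No methylation sensitivity, star activity, or vendor-database
  synchronisation in the digest module; linear molecules only.
- No thermodynamic PCR simulation (Tm, dimers, efficiency of binding).
- Copy-number results are only as good as the input Ct values and the
  constant-efficiency assumption; inhibition or efficiency drift across
  the dilution range biases extrapolation.
- Wet-lab stages of a DYZ1 characterisation (culture, cloning, Sanger
  chemistry, FISH imaging) are entirely out of scope.
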