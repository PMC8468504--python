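# Methods

This note documents the models, conventions and design choices behind
`ampminer`, in the order the pipeline applies them.

## ORF model

Transcripts are scanned in all six frames for ATG-initiated ORFs; every
ATG opens its own ORF (nested starts are all reported) running to the
first in-frame stop, or to the transcript end, in which case the ORF is
flagged `partial`. Only ATG initiation is considered — near-cognate
starts are a documented limitation, acceptable here because all target
precursor families begin with a canonical Met signal peptide. Codons
containing `N` translate to `X`. The default `min_aa = 50` admits the
smallest complete precursor architecture handled (22-residue signal +
42-residue defensin = 64 aa) while suppressing decoy micro-ORFs.
Coordinates are half-open on the forward strand and include the stop
codon, so `transcript[start:end]`, reverse-complemented for `−` ORFs,
re-translates to `protein + '*'`.

## Signal-peptide heuristic

External signal-peptide predictors are deliberately not a dependency;
the pipeline uses a transparent two-feature score over candidate
cleavage positions c ∈ [15, 30]:

* **h-region**: the best mean Kyte–Doolittle hydrophobicity over any
  8–12-residue window whose last residue lies 4–7 positions before c —
  the hydrophobic core of a real signal peptide abuts its C-region, and
  anchoring the window to c is what lets the score discriminate between
  nearby candidate positions;
* **(−3,−1) rule**: +1.0 when the residues at c−3 and c−1 are small
  ({A,G,S,C,T}), the classic von Heijne constraint.

The best-scoring position wins (smallest c on ties — ties occur when a
small residue recurs two positions into the mature region); the call is
rejected below θ = 1.5, a threshold on the Kyte–Doolittle scale (range
−4.5…+4.5) requiring a genuinely hydrophobic core. θ, the window bounds
and the position range are configuration, not constants; they are chosen
so that a textbook signal (M + basic pair + Leu-rich core + A-x-A) scores
≈ 3.8 + 1 and an acidic N-terminus scores far below 0. This heuristic is
an approximation of a trained predictor and is validated only against
the generator's templates (see below), not against curated signal-peptide
corpora.

## Mining tracks

Candidates come in two disjoint tracks. `piscidin_like` requires the
anchor motifs (default `FLVL` and `MAEPG`, both, exact match) within the
first 30 residues, total precursor length within [60, 120], and a
cysteine-free region after the predicted cleavage — piscidins are linear
cysteine-free helical peptides, so a single Cys disqualifies.
`cysteine_rich` requires a predicted signal peptide and ≥ 4 cysteines
after cleavage, with no motif requirement. Partial ORFs are excluded
from both tracks: a precursor must be complete. Exact motif matching
(no mismatches) is a reproducibility choice; fuzzy matching would need a
scoring model the source material does not provide.

## Family rules

Classification is a pure function of sequence and an editable rule set:

| family | convertase site | mature Cys | mature length |
|---|---|---|---|
| hepcidin | R-X-[K/R]-R | 8 | 20–32 (canonical 26, bonus evidence for a QSHL N-terminus) |
| leap2 | R-X-X-R | 4 | 40–52 (canonical 46) |
| defensin | none (no prodomain) | 6 | 36–48 directly after the signal |
| nklysin | — | ≥ 6 in a 70–80-residue window | saposin-domain proxy |
| piscidin_like | — | 0 | anchor motifs present |

For the convertase families, every site position is tried and the first
whose downstream region satisfies the count/length rule wins. Saposin
detection by cysteine count in a sliding window is a transparent proxy
for a profile-HMM domain search, which is out of scope. When several
rules fire, precedence is fixed: hepcidin > leap2 > defensin > nklysin >
piscidin_like — ordered from most to least specific evidence
(convertase + 8 Cys is harder to satisfy by chance than a motif pair).
Cysteine *spacing* is reported (`cys_signature`) but not enforced;
family-specific spacing grammars are left to the rule file.

## Peptide design

The parent peptide is the first 20 residues after the signal cleavage.
The truncation series emits every strict prefix ending in K or R and
keeps the three longest — a generalisation that, applied to the two
design parents, reproduces the published 17/13/10-residue series for
both (β: R17, R13, K10; γ: R17, K13, K10). C-terminal amidation is
carried as a flag only (charge +1 in the pH model, mass −0.98 Da);
nothing is assumed about the native processing of the mined precursors,
whose mature forms are uncharacterised.

## Physicochemical conventions

Two charge conventions coexist deliberately:

* **formal ("table") charge** z = (#K + #R) − (#D + #E), His and termini
  excluded — the convention under which cationic-AMP design tables print
  integer charges (a His-containing 10-mer with 2 K + 1 R is +3);
* **pH model**: per-group Henderson–Hasselbalch,
  z(pH) = Σ ±1/(1+10^(±(pH−pKa))), over the N-terminus, C-terminus
  (unless amidated) and D, E, C, Y, H, K, R side chains, with the
  Expasy-compatible single-pKa set (N-term 7.5, C-term 3.55, D 4.05,
  E 4.45, C 9.0, H 5.98, K 10.0, R 12.0, Y 10.0). z(pH) is strictly
  decreasing, so the pI is the unique zero, found by bisection on
  (0, 14) to 1e-3; when the curve never crosses zero (e.g. an amidated
  peptide with no acidic group) the boundary is returned with a warning.
  This per-group model approximates, but is not identical to, the
  position-specific Bjellqvist model used by the Expasy web tool.

Masses use Expasy-style average and monoisotopic residue tables plus one
water (18.0153 / 18.010565 Da); carbamidomethylation adds 57.02146 Da
per Cys to monoisotopic digest masses. The hydrophobic ratio counts
{A,C,F,I,L,M,V,W}; G, Y, P and H are excluded. In the rounded table
view, masses round to the nearest Da but the hydrophobicity percentage
is **truncated**, matching the online AMP-database calculator that such
design tables are quoted from (9/17 prints as 52 %, not 53 %).

Helix parameters use the Fauchère–Pliska octanol scale as tabulated by
Heliquest. H is the plain mean; µH is the Eisenberg vector mean at
δ = 100°/residue, normalised by N (so an 18-mer homopolymer, five full
turns, gives exactly 0). Wheel face angles are the smallest arc
containing all K/R (charged face) or all hydrophobic-set azimuths,
computed exactly via the largest circular gap; a face with no members is
`None` rather than 0.

## Proteomics and expression support

Tryptic digestion cleaves after K/R except before P, enumerating all
products with ≤ `max_missed` missed cleavages; 0-missed products tile
the parent exactly. Evidence matching treats an observed peptide as
supporting a candidate when it equals one of the candidate's tryptic
products. FPKM is the closed form count / ((L/10³)·(N/10⁶)); read
mapping itself is out of scope, the module takes a counts table.

## Synthetic data: what it emulates, and what it does not

The generator plants family-templated precursor ORFs (5′UTR + ATG…stop +
3′UTR, random strand, synonymous codons sampled uniformly) among decoys
that are either random-codon ORFs or non-coding sequence,
rejection-sampled so no six-frame translation contains an anchor motif.
Default conditions: 10 piscidin plants, 4 plants per cysteine-rich
family, 174 decoys — 200 transcripts with a ~13 % plant fraction, small
enough to exercise precision, with mining tested for recall = 1.0 and
precision ≥ 0.9 on the piscidin track.

Generator and detector agree **by construction**: the signal template is
M + two basic residues + a hydrophobic core + A-x-A (piscidin signals
start `MAEPGFLVL…`), which is exactly the h-core/(−3,−1) pattern the
mining heuristic scores. Two template details keep that agreement
airtight rather than statistical: the core fill alphabet {L,I,F,M}
excludes V (so `FLVL` cannot arise in non-piscidin signals) and excludes
W and all small residues (W is weakly scored by Kyte–Doolittle and
smalls would fake (−3,−1) sites); and the first 8 residues after the
true cleavage contain no small residues, so no spurious downstream
(−3,−1) pair can outscore the real site. Piscidin mature regions default
to 40–60 residues — the length of characterised piscidin-4-type mature
peptides — which also places full precursors inside the mining length
window. The divergence model (`mutate_plants`) substitutes unprotected
residues at a given rate, never touching anchor motifs, scaffold
cysteines, the initiator Met, the (−3,−1) context or convertase motifs.

Consequently, passing tests show the pipeline is *internally correct*
(each stage recovers exactly what the generative model encodes, and the
brute-force oracles agree), not that it would achieve the same recall on
real assemblies, where signal peptides are noisier than the template,
UTRs contain sequencing artefacts, and family architectures deviate from
the scaffold idealisation. Expression levels, read simulation and
assembly errors are explicitly not modelled.

## Problem sizes and numerics

Test and acceptance workloads are desk-scale by design: 200-transcript
pools, 100–200-case oracle sweeps (exhaustive six-frame ORF scan,
0.001-pH grid for pI, split-merge digestion, 1°-rotation wheel scan),
chosen as the smallest sizes at which the equivalences are convincing.
Determinism is end-to-end: a single integer seed drives generation, and
report bundles for identical configuration + seed are byte-identical
(hash-comparable); the run manifest records config, seed, version and
input checksums.
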