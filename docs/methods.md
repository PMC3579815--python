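# Methods

## Splice-site strength models

A splice site is modelled as a positional base-frequency matrix over a
fixed window anchored on the invariant dinucleotide: donor windows span
the last 3 exonic and first 6 intronic bases (−3..+6), acceptor windows
the last 12 intronic and first 2 exonic bases (−12..+2). The acceptor
window deliberately stops at intron position −12, the outer edge of the
splice-region footprint used for variant grouping (below); both
geometries are configurable per model.

Training is by counting with additive smoothing:
`f(b,i) = (count(b,i) + q) / (n + 4q)` with pseudocount `q = 0.5` by
default. The pseudocount's only job is to keep every frequency positive so
that information scores stay finite; results are insensitive to its exact
value at realistic training sizes.

Two scores are computed for a window sequence:

* **Consensus value (CV, %)** — the Shapiro–Senapathy-style normalisation
  `100·(s − s_min)/(s_max − s_min)` where `s` is the sum of observed-base
  frequencies and `s_min`/`s_max` are the sums of the per-position minima
  and maxima. The positionwise-argmax sequence scores exactly 100, the
  argmin sequence 0. A uniform matrix has `s_max = s_min` and is rejected
  as uninformative.
* **Individual information (Ri, bits)** — `Σᵢ (2 + log₂ f(bᵢ,i))`,
  additive over positions; a uniform model gives 0 bits for every window.
  The classical small-sample correction term is omitted: it is a constant
  offset at fixed training size and cancels in wild-type/mutant
  comparisons. This is a documented simplification, not an oversight.

Detection floors default to CV ≥ 70% and Ri > 0 bits. These are package
defaults for "the site is recognized", recorded in output metadata and
configurable; they are not estimates of any external program's internal
cutoffs, which are not public.

## Variant deltas and alternative sites

Percent differences follow the two conventions used when comparing
predictor output between wild-type and mutated sequences:

* PWM-type scores: `100·(SSPS_mut − SSPS_wt)/SSPS_wt`, defined only when
  the wild-type site is recognized (`SSPS_wt > 0`); a site absent from the
  mutated output is scored −100 exactly. When a mutated score is reported
  but merely small, the reported value is used as-is — the −100 convention
  applies only to exact absence.
* Information scores: `100·(2^(ΔRi) − 1)`, bounded below by −100 (open),
  unbounded above; ±1 bit maps to +100% / −50%.

Score *increases* are never called spliceogenic; only decreases are
compared against thresholds.

After applying a variant, the natural junction is re-located through the
edit: coordinates downstream shift by the net length change, and a
junction whose own bases were deleted (e.g. a delins removing the acceptor
AG) is clamped into the replacement span. Alternative-site scans cover
±500 bp around the (re-located) natural junction in the mutated sequence;
every same-type window at or above the floor, other than the natural
junction itself, is reported with its junction-to-junction distance in
mutated coordinates and tagged **cryptic** if the corresponding wild-type
junction also scores at/above the floor, otherwise **novel**. Ranking
helpers report each in vitro used junction's 1-based rank among candidates
by score and by absolute distance (ties share the better rank), because
neither "strongest candidate" nor "closest candidate" reliably identifies
the site actually used.

## Variant grouping

Group A: any affected base at intron positions ±1/±2 (the nearly invariant
GT/AG). Group B: any affected base in intron +3..+8 (donor side) or
−3..−12 (acceptor side), in the last 3 bases of an exon, or in the first 2
bases of an exon. A takes precedence over B; everything else is "other".
Membership is evaluated per affected base, so multi-base deletions
spanning a boundary are grouped by their most critical base.

## Transcript consequences

The HGVS subset grammar covers what splice-region work needs: `c.` SNVs,
deletions, insertions and delins with CDS-relative anchors and signed
intronic offsets; `r.` bracketed event lists mixing `=` (normal
transcript), deletions, intron retentions written as insertions of an
intronic span, and substitutions. Unicode minus signs are normalised to
ASCII hyphens and internal spaces dropped before parsing, since published
tables mix both. A trailing `"; ..."` annotation inside an `r.` event
(the variant shown within the retained intron) is stored verbatim and
never validated — the notation is not used consistently enough in source
material to warrant checking. Duplications, inversions and protein-level
parsing are out of scope; `p.` strings are emitted, never parsed.

Consequence prediction distinguishes two regimes:

* **Coordinate arithmetic only** (transcript without sequence, e.g. the
  bundled BRCA1/BRCA2 exon maps): frame status from the net coding-length
  change mod 3; `first_affected_codon = floor((c−1)/3) + 1` for the first
  altered base; `residues_deleted = nt/3` for in-frame deletions. The PTC
  position is reported as undetermined and emitted `p.` strings end at
  `fs`.
* **Full translation** (sequence available): the aberrant mature mRNA is
  reconstructed (deletions removed, retained intronic sequence copied in
  from the gene, substitutions applied), translated, and the first stop
  located. Frameshift `p.` strings are named at the first residue that
  actually *differs* from the wild-type protein (the junction codon may
  happen to re-encode the wild-type amino acid), with `fsX` counting from
  that residue to the stop — matching how protein-prediction servers
  annotate such events. In-frame deletions are additionally checked for a
  junctional stop codon.

Events touching the start or stop codon are flagged rather than
annotated. Note that `first_affected_codon` is always the codon of the
first altered nucleotide; the residue *named* in a translated `p.` string
can be downstream of it.

Clone-count proportions of allelic expression are rounded half away from
zero and accompanied by exact Clopper–Pearson 95% intervals
(statsmodels). Clinical classification follows the five-tier scheme:
spliceogenic variants are class 5 when normal transcript expression is
mono-allelic, class 4 when bi-allelic, "4 or 5" when not assessable;
non-spliceogenic variants are class 2 given an intronic location or a
benign missense prior (an external input, e.g. an alignment-based missense
classifier), and otherwise explicitly unclassified — never silently
defaulted.

## Benchmark procedure

Thresholds are calibrated per predictor as the minimum absolute percent
*decrease* over informative true-spliceogenic cells; the comparison at
classification time is inclusive (`|decrease| ≥ threshold`) so the
calibrating variant is itself called spliceogenic and sensitivity on the
calibration set is exactly 100% by construction. False-positive rates
divide spliceogenic calls by *informative* true-non-spliceogenic analyses
only; a predictor with no such analyses is reported undefined, as is a
threshold for a predictor with no informative spliceogenic decrease.

Calibrating and evaluating on the same small series is how such
benchmarks are reported in the clinical literature and is reproduced here
deliberately; it is optimistically biased, and `benchmark_loo` provides a
leave-one-out variant for comparison (diagnostic only, not the headline
path). Report tables round percentages to one decimal; underlying data
outputs keep full precision.

## Bundled study tables

The 24-variant BRCA1/BRCA2 series and its 13×9 prediction matrix are
shipped as TSV data. Exon structures are CDS-relative coordinate maps of
the classical transcript framings of the two genes; every boundary touched
by an event in the series is consistent with the deletion spans the series
itself reports (e.g. BRCA2 exon 5 = c.426..475, exon 23 = c.8954..9117).
5'UTRs are not represented (no variant in the series touches them) and
intron lengths are placeholders — only exon boundaries and splice-region
offsets enter any computation on these tables. Summary tallies
(19 spliceogenic; 16 producing PTC-containing aberrant transcripts; 2
up-regulating naturally occurring PTC isoforms; 1 in-frame deletion;
10 of 19 using alternative splice sites) are recomputed from the mRNA
descriptors, not stored: a variant counts as using an alternative site
when any of its aberrant events is a partial exon loss or an intron
retention, and its consequence category follows its first-listed aberrant
transcript, with the isoform-up-regulation flag taking precedence.

## Synthetic data

The generator emulates a compact clinical series: by default 5 exons of
80–200 nt and introns of 300–1200 nt (ample for ±500 bp scans), boundary
windows sampled from bundled consensus donor/acceptor frequency tables
(approximate human consensus compilations, smoothed at a notional n=200)
with GT/AG enforced exactly, a planted ATG, a terminal stop and no
internal in-frame stop. The default variant table mirrors the bundled
series' shape: 11 group A variants (spliceogenic by definition), 13 group
B variants whose ground truth is set by whether the mutated natural site
retains positive information under the generating model, and deep
controls. Prediction matrices plant their error structure explicitly:
spliceogenic cells are decreases of at least the separation floor
(default 30%), with one cell per predictor pinned exactly at the floor so
the calibrated threshold is known; non-spliceogenic cells cross the floor
with the configured false-positive probability (default 0.2) and otherwise
stay strictly inside it.

One `numpy` Generator seeded per bundle drives every draw, and the seed
is recorded in the manifest; regenerating with the same seed reproduces
all files byte-identically.

What the generator does *not* emulate: exonic splicing enhancers and
silencers, branch points, polypyrimidine-tract strength variation beyond
the frequency model, NMD efficiency, tissue-specific factors, or
correlated errors between predictors. Passing tests on synthetic material
therefore demonstrates correctness of the pipeline's bookkeeping and
statistics, not predictive performance on real genes — the bundled
clinical tables carry that part.

## Numerical choices and problem sizes

* Coordinates are gene-local, 0-based, half-open, 5'→3' (no genomic
  minus-strand logic); donor junctions index the first intronic base,
  acceptor junctions the first exonic base.
* Percentages in reports: one decimal; clone-count percentages: integer,
  half away from zero.
* Scan/score equivalence and scanning oracles are exercised on ≤2 kb
  sequences; translation-oracle checks run on ~1000 random synthetic
  transcripts; planted false-positive recovery uses 1000 control variants
  and a 3-standard-error band. These sizes make the full suite run in a
  few seconds while keeping every statistical check well-powered.

## Known limitations

* The in-house CV/Ri scorers are deliberately simple stand-ins for the
  heterogeneous model families of published predictors (maximum-entropy,
  neural-network, …); their absolute scores are not comparable to any
  external program's output, only their wild-type/mutant differences are
  meaningful within the package.
* Single-transcript only: no isoform-aware scoring, no genome-wide VCF
  annotation.
* The benchmark's same-set calibration bias is inherited by design (see
  above).
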