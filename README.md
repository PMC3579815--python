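# splicebench

Tools for the computational side of clinical splice-variant work-up:
scoring splice-site strength, quantifying how a variant changes it,
predicting the transcript and protein consequence of the observed mRNA
change, and benchmarking splice-effect predictors under a
100%-sensitivity constraint.

The package is aimed at people who evaluate unclassified variants (UVs) in
disease genes — the motivating material is a series of 24 UVs at BRCA1 and
BRCA2 donor/acceptor splice sites, bundled with the package as plain TSV
tables: each variant's in vitro splicing outcome (observed mRNA changes,
allelic expression of the normal transcript, clinical class) and a
13-variant x 9-predictor matrix of percent score differences from nine
splice-prediction programs (SSF, MES, NNSPLICE, GS, HSF, NG2, SV, SP,
ASSA).

## What it computes

**Site strength.** A positional base-frequency model over a window anchored
on the invariant GT/AG dinucleotide (donor −3..+6, acceptor −12..+2 by
default) is scored either as a *consensus value*

    CV = 100 · (Σᵢ f(bᵢ,i) − Σᵢ minᵦ f(b,i)) / (Σᵢ maxᵦ f(b,i) − Σᵢ minᵦ f(b,i))

or as *individual information* in bits, Ri = Σᵢ (2 + log₂ f(bᵢ,i)),
where a 1-bit change corresponds to a 2-fold change in predicted
spliceosome binding affinity.

**Variant deltas.** PWM-style scores are compared as
`100·(SSPS_mut − SSPS_wt)/SSPS_wt`; information scores as
`100·(2^(Ri_mut − Ri_wt) − 1)`. An analysis is *informative* only if the
wild-type site is recognized (score at/above the detection floor). The
±500 bp around a damaged natural site can be scanned for alternative
junctions, tagged *cryptic* (already present in the wild type) or *novel*
(created by the variant).

**Benchmarking.** Per predictor, the classification threshold is the
smallest absolute percent decrease observed for an in vitro spliceogenic
variant — this anchors sensitivity at 100% by construction — and
specificity is then measured as the false-positive rate among informative
true non-spliceogenic variants.

**Consequences.** HGVS `c.` and `r.` descriptors (SNV/del/ins/delins;
exon skipping, partial exon loss, intron retention, substitution) are
parsed, the aberrant mature mRNA is reconstructed, and the protein outcome
(frameshift with premature termination codon, in-frame deletion, missense/
silent) is derived by frame arithmetic and, when sequence is available,
translation.

**Synthetic data.** A seeded generator produces multi-exon genes with
consensus GT/AG sites, splice-region variant tables with ground-truth
labels, and prediction matrices with planted informativeness and
false-positive structure, so the whole pipeline is testable end to end.

## Worked example

```python
>>> import splicebench as sb
>>> from splicebench.datasets import load_benchmark_matrix, summarize_study
>>> matrix = load_benchmark_matrix()
>>> result = sb.benchmark(matrix)
>>> result.calibration.thresholds.round(2)
SSF           6.30
MES          31.50
NNSPLICE      9.80
GS          100.00
HSF           4.10
NG2          29.00
SV            6.70
SP          100.00
ASSA         81.05
dtype: float64
>>> result.calibration.fully_informative
['MES', 'HSF', 'ASSA']
>>> result.fp_rates
          rate  fp_num  fp_den
SSF        0.0       0       3
MES       40.0       2       5
NNSPLICE  50.0       2       4
GS         0.0       0       3
HSF        0.0       0       5
NG2       50.0       1       2
SV         0.0       0       4
SP        20.0       1       5
ASSA       0.0       0       5
```

Reading: HSF needed only a 4.1% score decrease on its weakest true
spliceogenic variant (so 4.1% becomes its spliceogenicity threshold),
while GS and SP only ever reported complete site loss (−100%). With those
thresholds, MES mislabels 2 of its 5 informative non-spliceogenic variants
as spliceogenic (40% false-positive rate); HSF and ASSA combine full
informativeness with a 0% false-positive rate. Only MES, HSF and ASSA
recognized every natural splice site in the wild-type sequences.

Consequence annotation works directly from the observed mRNA change:

```python
>>> t2 = sb.datasets.transcript_for("BRCA2")
>>> (c,) = sb.predict_consequence(t2, sb.parse_hgvs_r("r.[8954_9004del]"))
>>> c.kind, c.first_affected_codon, c.residues_deleted
('inframe_del', 2985, 17)
>>> summarize_study()["n_spliceogenic"], summarize_study()["n_ptc_transcripts"]
(19, 16)
```

(The 51-nt in-frame loss removes 17 amino acids starting at codon 2985 —
inside the DNA-binding domain of BRCA2.)

A CLI mirrors the library (`splicebench simulate|score|scan|calibrate|
evaluate|consequence`), e.g.:

```bash
splicebench simulate --seed 3 --out sim/            # synthetic bundle
splicebench evaluate --report report.md --fmt md    # bundled benchmark
splicebench consequence --gene BRCA2 --rchange 'r.[8954_9004del]'
```

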