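# rhizotox

Integrative analysis of early rice (*Oryza sativa*) root transcriptome
responses to rhizotoxins — heavy metals and metalloids (Cu, As(V), Cd, Hg,
Cr, V) and allelochemicals (ferulic acid, juglone) — for researchers
studying general stress responses and screening stress-specific expression
biomarkers.

## What it computes

**Expression classification.** Each stress is profiled at 1 h and 3 h with
triplicate control/treated intensity arrays. After a detection filter
(signal ≥ 100 in at least one sample) and optional joint quantile
normalization, each gene gets a per-stress signed fold change
FC = r if r ≥ 1 else −1/r (r = treated/control mean; the larger-|FC|
timepoint is reported), a control-vs-treated Kruskal–Wallis p, and a
per-stress Benjamini–Hochberg q. Genes are then classified:

* **GSR** (general stress response): FC ≥ 2 under all eight stresses (q < 0.05)
* **uniquely regulated**: |FC| ≥ 2 under exactly one stress, |FC| ≤ 1.4 under the others
* **background**: |FC| ≤ 1.2 under all stresses
* **low-regulated**: 1.2 < FC < 2 under all stresses

**Downstream characterization of the classes.**

* *Promoter motifs*: IUPAC consensus scanning (W-box `TTGACY`, ABRE-like
  `BACGTGKM`, RWRE `CGCGTT`, CGCG box `SCGCGCS`) on both strands of 1 kb
  promoters; enrichment = difference of per-gene presence fractions, tested
  by label permutation with the add-one p-value.
* *Gene architecture*: intron counts and total intron length from GFF3;
  intronless fractions by pooled two-proportion z-test; Kruskal–Wallis +
  Dunn across classes; Mann–Whitney on total intron length between the top
  and bottom 50% of genes by FC.
* *Molecular evolution*: codon alignments by back-translation of protein
  alignments; Ka/Ks per ortholog pair with Nei–Gojobori (1986) counting
  (equal-weight pathway averaging, stop-aware) and Jukes–Cantor correction
  K = −(3/4)·ln(1 − 4p/3); rank-based category comparisons.
* *Networks*: degree-ranked hubs and "terminal regulators" (TF/kinase nodes
  whose neighbors include no other regulator) on an undirected edge list.
* *Biomarker screen*: ΔΔCt quantification (fold = 2^(−ΔΔCt), α-tubulin-style
  reference gene) and a two-stage specificity screen — unique induction
  under a single stress, then retained specificity under combined 4-of-5
  metal panels via the ratio (min fold over panels with the target stressor)
  / (max fold over panels without it).

A synthetic-data module generates every input with known ground truth,
emulating the 8-stress × 2-timepoint × 3-replicate design, so the whole
pipeline is testable against planted labels.

## Worked example

```bash
python analysis/01_simulate.py --seed 1           # synthetic study inputs
python analysis/02_classify_expression.py         # classify + summarize
```

The classification step prints (seed 1, noise 0.05):

```
planted-label recovery: 97.71% (350 planted genes)
basal expression ranking (highest first): ['background', 'GSR_up', 'low_regulated']; Kruskal-Wallis p = 6.41e-14
published-table identities: uniquely-up total 219, uniquely-down total 370, generally regulated 577
```

i.e. ~98% of the 350 planted class labels are recovered under measurement
noise, background genes show the highest basal expression (the expected
pattern for stress-inducible vs constitutive genes), and the summary
arithmetic reproduces the published per-stress count table's non-redundant
totals. The remaining drivers (`03`–`07`) run the motif, architecture,
Ka/Ks, network and biomarker analyses the same way; `rhizotox run-all`
(or `rhizotox --help`) exposes the same stages as a CLI.

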