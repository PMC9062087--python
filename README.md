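# hicdelta

Comparative 3D-genome analysis of a paired tumor/normal sample from Hi-C
contact maps: matrix balancing, A/B compartment switches, TAD boundary
alterations, chromatin-loop comparison, translocation detection with
whole-genome-sequencing (WGS) confirmation, and the contingency statistics
that tie each structural level to differential gene expression.

It is written for computational biologists who have HiC-Pro-style sparse
contact matrices for two conditions (plus loop calls, SV calls and a
differential-expression table from the usual upstream tools) and want the
full downstream comparison as a tested, scriptable pipeline. Because the
raw data such analyses are built on is rarely portable, the package ships a
seeded synthetic-data generator that emulates every statistical structure
the analysis relies on — power-law distance decay, compartment plaid, TAD
blocks, loop dots, per-bin bias, Poisson counts, planted translocations,
and a matched expression table — with machine-readable ground truth, so
every stage is verifiable end to end.

## The analysis

For a contact matrix *W* over fixed genomic bins:

- **ICE balancing** finds per-bin biases *b* with
  *W*<sub>raw</sub>(*i*,*j*) = *b*<sub>*i*</sub>*b*<sub>*j*</sub>·*W*<sub>norm</sub>(*i*,*j*),
  iterating until the unmasked row sums are equal (coefficient of
  variation below a tolerance).
- **A/B compartments** are the sign of the leading eigenvector (PC1) of
  the Pearson correlation of the observed/expected cis map, per
  chromosome, at 500 kb; bins whose label flips between conditions are
  B2A ("activated") or A2B ("deactivated"), and the activation ratio is
  length(B2A)/length(A2B).
- **TAD boundaries** are valleys of the insulation score (mean signal in
  a 10-bin square sliding along the diagonal at 50 kb), located as
  minus-to-plus zero crossings of a delta track and matched one-to-one
  across conditions; TADs touched by condition-specific boundaries are
  "altered".
- **Specific loops** are loops unique to one condition by *both* anchors
  (one-to-one joint anchor matching at 10 kb).
- **Translocations** are rectangular trans-contact hotspots at 40 kb that
  are kept only when *double-confirmed*: a span edge (± 1 bin) contains a
  WGS breakpoint. Confirmed blocks are masked from all further analysis.
- **Integration** cross-tabulates genes (by midpoint bin) against each
  structural axis: up/down ratios per switch class and DEG/NDEG 2×2
  tables, each with a Pearson chi-square against the stable group.

## Worked example

```bash
hicdelta simulate --seed 1 --out results/data
hicdelta run-full --data-dir results/data --out-dir results/run
```

or, as stepwise narrative scripts, `python analysis/01_simulate.py --seed 1`
through `analysis/06_expression_integration.py`. On seed 1 the run prints
(abridged):

```
planted switches: 35 B2A bins, 24 A2B bins (of 200)
switched to A (activated): 17.0% of the genome
switched to B (deactivated): 11.0% of the genome
boundaries: 154 (normal) vs 149 (tumor); shared 138; specific 16 / 11
median TAD size: 650 kb
translocation chr2:10000000-11200000 x chr3:7960000-8800000 fold 7.7 [double-confirmed]
loops: 75 vs 75; specific 8/8
up/down ratio [A2B]: 0.029   (chi2 82.85, p 8.8e-20)
up/down ratio [B2A]: 11.059  (chi2 89.88, p 2.5e-21)
DEG/NDEG [loop]: altered 6.5 vs stable 1.853 (chi2 6.05, p 0.014)
```

Reading this: the pipeline recovered the planted compartment switches
(17% activated vs 11% deactivated of a 100 Mb toy genome), located the
planted TAD boundary alterations and the one planted translocation (its
detected span edges sit within one 40 kb bin of the truth, and a WGS
breakpoint confirms it), and the expression integration shows the planted
directionality — activated compartments are strongly up-skewed, deactivated
ones down-skewed, and genes at specific-loop anchors are the most enriched
for differential expression.

The structured summary is written to `results/run/report.json`; per-stage
caches (`stage_*.json`, bedGraph-like TSV tracks) sit alongside it. Reruns
with the same seed are byte-identical.

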