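# glycoshift

Differential N-glycosylation site occupancy analysis for paired-design,
label-free proteomics — with a fully synthetic glycoproteome generator so the
entire pipeline can be exercised and validated without any deposited
mass-spectrometry data.

## The problem

N-glycans are attached to Asn residues inside the acceptor sequon
**N-X-S/T (X ≠ Pro)**. When the supply of the lipid-linked oligosaccharide
(LLO) donor is limited — as in congenital disorders of glycosylation type I —
sites compete for a scarce substrate and some remain unoccupied
(*hypoglycosylation*). Two protein features govern who loses:

* **sequon efficiency** — NxT sequons are filled more efficiently than NxS;
  an aromatic residue (F/Y/H/W) at position −2 helps; non-canonical sequons
  are weakest;
* **multiplicity** — the number of glycosylation sites per protein. A protein
  with many sites accumulates more unoccupied positions under the same
  per-site loss, and is degraded more as a consequence.

`glycoshift` implements the complete label-free analysis that detects these
effects from two experiments on the same tissue:

1. **Total proteome** (protein abundance): complete-case filtering (a protein
   is tested only if detected in all samples — no imputation, ever), a paired
   two-sided t-test on log2 intensities within litter pairs, and
   Benjamini–Hochberg q-values (decreased/increased at *q* < 0.05).
2. **Glycoproteome** (deglycosylated site-level peptides): a site is
   *testable* when detected in ≥ 3 of 4 control samples; testable sites get a
   two-sided Welch t-test on detected log2 values (*p* < 0.05); a feature seen
   in ≥ 3 samples of one genotype and zero of the other is called
   `exclusive_control` / `exclusive_mutant` by the detection rule alone.

On top of the calls it computes the susceptibility statistics: the
evidence-based **reference glycoproteome** (sites detected in ≥ 2 control
samples) and per-protein multiplicity; novel-site calling against known-site
lists; Fisher-exact fold enrichment of glycoproteins among decreased proteins
and of high-multiplicity proteins among decreased glycoproteins; Mann–Whitney
multiplicity comparisons (exact for small groups); positional sequon motif
enrichment (−2 non-aromatic, +2 Ser, full position × residue tables); the
Pearson correlation between multiplicity and the fraction of NxS sites with
decreased occupancy; annotation-set (e.g. IgSF-CAM) enrichment; and an
occupancy cross-reference — a decreased glycosite whose *unmodified*
counterpart peptide appears in ≥ 3 mutant samples but never in controls is
called `unoccupied_in_mutant`, the strongest label-free evidence that the
site lost its glycan rather than its protein.

## The synthetic glycoproteome

`SimConfig`/`simulate_dataset` generate a ground-truthed study: proteins with
1 + negative-binomial site multiplicity; per-site transfer efficiency *e* from
sequon class and −2 context; mutant occupancy

```
o_mut = e · max(0, 1 − κ·s·(1−e)),      o_ctrl = e
```

under global stress *s* with sensitivity κ (inefficient sequons lose
disproportionally more, clipping at fully unoccupied); protein degradation
`r = exp(−λ·Σ(o_ctrl − o_mut))`; log-normal intensities with litter effects
and replicate noise; and missing-not-at-random dropout
`P(observed) = logistic((log2 I − τ)/ω)`. A site with zero occupancy is
MISSING, never zero — an absent species cannot ionize.

## Worked example

`examples/` holds one short script per capability. The end-to-end run
(`python examples/full_synthetic_pipeline.py`) simulates 800 proteins at the
default mild stress and prints:

```
reference glycoproteome: 702 sites on 289 glycoproteins
novel sites: 168 (23.9% of the reference)
glyco partition: {'testable': 555, 'exclusive_control': 24, 'exclusive_mutant': 3, 'filtered_out': 286}
glyco status calls: {'decreased': 210, 'exclusive_control': 24, 'exclusive_mutant': 3, 'unchanged': 345}
occupancy calls: {'unchanged': 348, 'occupancy_reduced_unconfirmed': 233, 'unoccupied_in_mutant': 1, 'protein_level_change': 0}
NxS sites decreased vs multiplicity: Pearson r=0.882 p=3.75e-03 over 8 bins
  -> NxS sequons on highly glycosylated proteins lose occupancy most often
multiplicity of proteins with decreased glycopeptides: 3.89 vs 1.62 (Mann-Whitney p=2.42e-20)
```

Reading the numbers: 234 of 582 site calls are decreases or control-exclusive
losses while only 3 go the other way — the hallmark of a global occupancy
defect; proteins carrying those sites average 3.9 glycosylation sites against
1.6 for the rest, and the share of NxS sequons losing occupancy climbs with
multiplicity (r = 0.88), i.e. weak sequons on heavily glycosylated proteins
are hit first.

The same stages are available from the shell:

```bash
glycoshift simulate --seed 1 --n-proteins 800 --out-dir sim/
glycoshift diff-glyco --glyco-table sim/glyco_quant.tsv --design sim/design.tsv --out-dir out/
glycoshift run-all --seed 1 --out-dir full_run/
```

All inputs and outputs are plain tab-separated text (plus FASTA); missing
values are `NA` on disk and are preserved — no stage imputes.

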