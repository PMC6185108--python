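# Methods

This note documents the statistical procedures, the generative model behind
the synthetic glycoproteome, the numerical conventions, and the design
choices that were genuinely open — together with what the simulation-based
validation does and does not establish about real data.

## Data model and conventions

Intensities are stored on the raw scale and log2-transformed only inside
statistical routines, so file round-trips are lossless. A missing cell means
*not detected*; it is encoded `NA` (or an empty cell) on disk and `NaN` in
memory, is counted and propagated but never replaced by a number: the whole
pipeline is imputation-free, and filters are defined on detection patterns
instead. Protein coordinates are 1-based and inclusive, with a glycosite
addressed by the position of its Asn (`protein_id:position` in feature ids),
matching UniProt site conventions.

## Sequon annotation

A canonical sequon is N-X-S/T with X ≠ Pro; the scanner reports every match,
including overlapping ones, and classifies the +2 residue into NxT versus
NxS. Sites addressed from evidence tables may also be non-canonical (anything
failing the rule, including Pro at +1 or a truncated C-terminal window); they
are retained throughout — non-canonical sequons recur among newly identified
sites and carry the weakest transfer efficiency. The −2 residue is recorded
with its aromaticity (aromatic = F, Y, H, W); sites at positions 1–2 have an
undefined −2 context and are excluded from −2-dependent analyses only, never
from anything else.

The **reference glycoproteome** is evidence-based: a site enters it when its
deglycosylated peptide is detected in at least 2 of the 4 control samples
(mutant-only detections do not qualify). Raising that threshold can only
shrink the reference (a property the tests check). Multiplicity — the number
of distinct reference sites per protein — is the pipeline's central
covariate; a scanner-based count (`scanned_multiplicity`) is reported
alongside but enrichment analyses use the evidence-based count. Sites absent
from every user-supplied known-site list are tagged *novel*.

## Differential statistics

**Total proteome.** Only proteins detected in all eight samples are tested
(complete-case rule). The test is a paired two-sided t-test on within-pair
log2 differences (pairs are litters), with Benjamini–Hochberg q-values over
the tested set; decreased/increased means q < 0.05 with the corresponding
sign. BH was chosen as a deterministic, assumption-light FDR procedure.
Zero-variance difference vectors are flagged `degenerate_zero_variance` and
assigned p = 1 when the shift is zero, or the smallest positive float
otherwise (detected by a 1e-9 tolerance on the log2 scale, which absorbs
floating-point noise in exact-ratio constructions). Optional per-sample
median centering on the log2 scale exists but is off by default: the upstream
label-free pipeline this mirrors applies no cross-sample normalization.

**Glycosites.** A site is testable with ≥ 3 of 4 control detections. The test
is a two-sided unpaired t-test on detected log2 values only, Welch's form by
default (a config flag restores the pooled-variance form); at least two
detected values per genotype are required, otherwise the site is left
`unchanged` with a `low_coverage` flag. Significance is p < 0.05 with no FDR
step; q is undefined in this branch. Features detected in ≥ 3 samples of one
genotype and zero of the other bypass the test entirely and are reported as
`exclusive_control` / `exclusive_mutant` — a detection-pattern rule, not a
test outcome, so no pseudo-p-values are invented for them. The four buckets
(testable, the two exclusives, filtered-out) partition every input feature.

The glyco branch is unpaired because the glycoproteomic experiment profiles
*different animals* than the total proteome; the synthetic generator encodes
the same asymmetry (below), which is what keeps the unpaired test calibrated.

## Occupancy cross-reference

For a decreased or control-exclusive glycosite, the unmodified counterpart
peptide in the total proteome is only observable where the site is
*unoccupied*. A counterpart detected in ≥ k mutant samples (k = 3, mirroring
the exclusive-detection rule) and zero controls yields the call
`unoccupied_in_mutant`. When that rule fails and the parent protein is itself
decreased at q < 0.05, the site is classified `protein_level_change` — an
added disambiguation category, since a protein-level drop explains a glyco
drop without any occupancy change. Everything else is
`occupancy_reduced_unconfirmed`: label-free MS cannot distinguish a
never-ionizing peptide from an absent one. Matching is by site key only;
tryptic-boundary bookkeeping (missed cleavages, shared peptides) is out of
scope.

## Enrichment statistics

All categorical contrasts are two-sided Fisher exact tests on 2×2 tables.
The headline effect size is **fold enrichment** — hit fraction in the set
over hit fraction in the background (which contains the set) — with the odds
ratio reported alongside; at multiplicity threshold 1 the decreased-set fold
is 1 by construction. Degenerate tables (an empty row or column) carry no
information and get p = 1; a threshold no protein reaches anywhere is
reported with fold 0 and p = 1 rather than as an error. The background for
protein-level enrichment defaults to all tested (complete-case) proteins.

Group multiplicity comparisons use the Mann–Whitney test: exact by full
labeling enumeration (midranks, so ties are handled identically in the
statistic and its null distribution) whenever the smaller group has ≤ 8
members and the labeling count stays below 5·10^5; otherwise the
tie-corrected normal approximation. "Unchanged" sets for every contrast are
all reference features not called decreased or increased (the inclusive
reading — filtered-out reference sites count as unchanged); a protein counts
as having decreased glycosylation when at least one of its sites is decreased
or control-exclusive.

Motif analysis contrasts decreased against unchanged sites per position
(−5…+5 relative to the Asn) and residue, with two headline features: a
non-aromatic −2 residue and Ser at +2 (the NxS motif). Position × residue
count matrices are emitted for logo-style display.

**NxS–multiplicity correlation.** Sites are binned by parent-protein
multiplicity (1…7, ≥ 8 pooled at x = 8; bin value as x; bins with fewer than
3 denominator sites dropped). The default construction
(`fraction_of_nxs`) plots, per bin, the percentage of NxS sites that are
decreased (and, as the second series, unchanged): under the degradation
model, occupancy loss at weak sequons compounds with multiplicity, so the
decreased percentage rises with multiplicity. The alternative construction
(`nxs_share_of_series`) — the NxS share *within* the decreased set per bin —
is available as a mode flag; it is flatter by construction, because
multiplicity-driven protein degradation eventually drags all sequon classes
into the decreased set at the same rate. Pearson r with its two-sided p is
computed per series over the (bin, percentage) points; a zero-variance series
is defined as r = 0, p = 1 rather than NaN.

Annotation-set enrichment (e.g. a cell-adhesion family membership list) is
the same Fisher machinery applied to any user-supplied protein set, mapped to
site features through the parent protein.

## The synthetic glycoproteome

The generator emulates a two-genotype (4 control vs 4 mutant, litter-paired)
label-free study of a mild, global N-glycosylation defect.

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 2000 | proteome size |
| `glycoprotein_fraction` | 0.4 | share of proteins carrying sites |
| `multiplicity_mean`, `multiplicity_dispersion` | 1.8, 1.0 | multiplicity = 1 + NB(mean, dispersion), capped at 16 |
| `sequon_class_probs` | NxT 0.45, NxS 0.45, non-canonical 0.10 | per-site class draw |
| `minus2_aromatic_prob` | 0.15 | aromatic −2 contexts |
| `efficiency` | NxT 0.98, NxS 0.92, non-canonical 0.70 | transfer efficiency e; +0.02 if −2 aromatic, capped 0.995 |
| `stress` (s) | 0.5 | global LLO-limitation stress in [0, 1] |
| `sensitivity` (κ) | 3.0 | amplifies occupancy loss at inefficient sequons |
| `degradation_rate` (λ) | 1.0 | protein loss per expected newly unoccupied site |
| `abundance_log2_mean/sd` | 20 / 2 | log-normal protein abundance |
| `replicate_sd`, `pair_effect_sd` | 0.25 / 0.3 | technical and biological (litter) log2 noise |
| `site_ionization_log2_sd` | 1.0 | fixed per-peptide response offset |
| `detection_midpoint` (τ), `detection_width` (ω) | 18 / 1 | MNAR dropout: P(observed) = logistic((log2 I − τ)/ω) |

Occupancy: `o_ctrl = e`, `o_mut = e·max(0, 1 − κ·s·(1−e))` — the simplest
form in which loss grows with sequon inefficiency and clips at fully
unoccupied. Degradation: `r = exp(−λ·Δu)` with Δu the summed per-site
occupancy loss, so multiplicity acts only through the number of newly
unoccupied sites. Intensities: protein log2 intensity = abundance + litter
effect + replicate noise, mutants shifted by log2 r; a glycosite adds
log2(occupancy) and its ionization offset; the unmodified peptide of the same
site uses log2(1 − occupancy) and shares the offset (it is the same peptide
backbone). Zero occupancy maps to MISSING — an absent species cannot be
measured — never to intensity 0.

Two structural choices matter downstream. First, the glycoproteomic samples
are *distinct animals*: their biological effects are drawn independently per
sample, while the total proteome (and its unmodified peptides) share litter
effects within pairs. This mirrors the emulated study design and is exactly
what makes the unpaired Welch test calibrated in the glyco branch — with
shared litter effects the test would be strongly conservative, since the
effects cancel in the group-mean difference but inflate the variance
estimate. Second, protein backbones contain no Asn outside the placed sites,
so the ground truth is unambiguous: every scannable sequon is a true site.
Real proteomes contain many never-glycosylated sequons; analyses that
contrast scanned against evidence-based multiplicity will therefore look
cleaner here than on real data.

Everything is drawn from a single seeded generator; a config reproduces its
dataset, and the orchestrated pipeline its entire output directory, byte for
byte.

### What the validation shows — and does not

The test suite checks the exact tests against exhaustive enumeration oracles
(every 2×2 table with total ≤ 40; all Mann–Whitney group shapes ≤ 6 vs 6; BH
against the hand-written step-up formula), the scanner against a naive
all-windows rule on 1,000 random sequences, and the filters against packaged
hand-derived fixtures. Simulation-based checks then validate calibration and
recovery: with stress and degradation switched off, the glyco branch calls
about 4% of testable sites at p < 0.05 and shows no multiplicity signal; under
default stress, the decreased share of significant site calls exceeds 70% and
the decreased-series NxS–multiplicity correlation is positive in essentially
every run.

Two power limitations of the *default study conditions* (not of the methods)
are worth stating plainly. With four pairs, the paired t-test has three
degrees of freedom, and BH at q < 0.05 over ~900 complete-case proteins
rejects only extreme effects — single runs typically yield a handful of
decreased proteins at q < 0.05 (or none), too few for protein-level Fisher
enrichments to reach small p-values reliably; MNAR dropout compounds this by
preferentially ejecting the strongly decreased high-multiplicity proteins
from the complete-case set. And the NxT/NxS efficiency gap (0.98 vs 0.92)
with κ·s = 1.5 produces a +2 Ser fold enrichment of only ≈ 1.1–1.2 among
decreased sites, so that contrast attains p < 0.01 only in a minority of
runs at this sample size. The acceptance script therefore reports the
protein-level enrichment structure on the nominally decreased set (p < 0.05,
negative fold change) alongside the q-based DAP count.

### Occupancy-recovery scenario

Under the defaults no site is fully de-occupied (κ·s·(1−e) < 1 for every
efficiency class), so the cross-reference recovery check uses a
strong-stress scenario chosen by design calculation: s = 1, κ = 60 (fully
de-occupying canonical sequons of efficiency ≤ 0.983), λ = 0 (no protein-level
confound) and ω = 0.5 (sharper detection). A counterpart is *informative*
when its expected log2 intensity — abundance + degradation shift +
log2(1 − occupancy) + ionization offset, noise-free — clears τ by 2ω in
mutants and stays 2ω below τ in controls; only such peptides can witness an
occupancy loss as an exclusive detection pattern. Among truly unoccupied
sites with informative counterparts, well over 80% are recovered as
`unoccupied_in_mutant`.

## Numerical choices

* Fisher two-sided p sums hypergeometric probabilities ≤ the observed
  table's (scipy); the test oracle re-derives it in exact integer arithmetic.
* Exact Mann–Whitney two-sidedness is |U − n₁n₂/2| ≥ |U_obs − n₁n₂/2| with a
  1e-9 slack so midrank arithmetic cannot miss exact ties.
* Result tables serialize floats at full precision (p-values re-parse to
  within 1e-9); `NA` is the only missing marker.
* Welch p on a zero-variance testable row with equal means is defined as 1.
* Problem sizes used by the validation suite: 2,000-protein simulations for
  calibration/recovery (10–20 seeds), 250–350-protein simulations for
  orchestration and determinism checks.

## Known limitations

No peptide-level chemistry is modeled (digestion, missed cleavages, charge
states, deamidation mass shifts, lectin capture bias); one feature per site
is assumed. The degradation model is memoryless in multiplicity and ignores
folding feedback (consistent with the emulated setting, where ER stress was
not a factor). Normalization beyond optional median centering, empirical-
Bayes variance moderation, and batch correction beyond the pairing design are
deliberately out of scope.
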