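# drwhite

Simulation and analysis toolkit for **single double-strand-break (DSB)
reporter assays in facultative heterochromatin**, built around the
DR-*white* reporter: an I-SceI site embedded in a *white* gene with a
downstream i*white* homology donor, integrated in *Drosophila* euchromatin
or polycomb-domain heterochromatin. After I-SceI cleavage, the repair
pathway is read out from the sequence of the repaired junction:

- **HR** (homologous recombination with the i*white* donor) removes the
  I-SceI recognition site — a fixed **23-nt deletion** spanning the cut;
- **NHEJ** (non-homologous end joining) leaves small indels (≤ 25 bp),
  overwhelmingly 1-bp deletions;
- **MMEJ** (microhomology-mediated end joining) produces deletions whose
  junction carries **≥ 2 bp of flanking microhomology**.

The package is aimed at people developing or benchmarking DSB-repair
analysis workflows: every input the analysis consumes (amplicon reads,
aggregate trace profiles, repair-focus trajectories, ChIP-qPCR plates, ROI
intensity tables) can be generated synthetically with known ground truth
and realistic effect sizes, and every analysis step is a tested, reusable
function.

## What is implemented

**Junction analysis.** Reads are anchored on primer-proximal reference
segments (outside the HR-deleted window, so HR products stay alignable) and
compared with the reference by longest-common-prefix/suffix arithmetic.
For a deletion `[s, e)` the caller reports its left-aligned placement, its
**microhomology** `m` — the largest `m` with `ref[s:s+m] == ref[e:e+m]`,
equivalently the number of equivalent placements minus one — and its
distance to the cut, measured from the whole shift-equivalence region so
that a shiftable junction near the cut is retained regardless of alignment
convention.

**Pathway classification.** Junctions further than 10 bp from the cut are
filtered out; the 23-nt HR signature wins unconditionally; remaining pure
deletions with `m ≥ 2` are MMEJ; all other indels ≤ 25 bp are NHEJ; larger
indels are tallied separately.

**Trace decomposition.** A TIDE-style estimator: the 4-channel trace
downstream of the cut is decomposed over indel-shifted reference profiles
(offsets −25..+25) by nonnegative least squares,

    min_w || signal − Σ_d w_d · profile_d ||²,  w_d ≥ 0,

with the −23 component read as HR and the remaining edited weight as NHEJ.

**Focus dynamics.** Repair-focus trajectories (inside / outside a polycomb
body / not detectable / resolved, on a 5-min imaging grid) with summary
statistics: fraction outside at a query lag, median focus lifetime,
accumulation fraction, and a two-sided chi-square comparison between
conditions.

**qPCR quantification.** ΔΔCt ChIP enrichment (IP/input = `2^(Ct_input −
Ct_IP)`, normalized to an internal-control locus), ratio paired t-tests on
log ratios, spike-in antibody-specificity panels, RT-qPCR knockdown levels
(`2^−ΔΔCt`), and relative-viability arithmetic for genetic crosses.

## Worked example

```sh
drwhite all --out run1
cat run1/report.txt
```

which prints (defaults: 2000 simulated reads with HR : NHEJ : MMEJ =
0.20 : 0.75 : 0.05, 2000 focus tracks, 13 qPCR replicates, 300 cells):

```
drwhite 0.1.0  (config f5de657c9470c4f9)

Repair-product classification (sequencing arm)
  reads retained        2000/2000
  repaired              100.0%
  HR of repaired        20.1%
  NHEJ of repaired      74.4%
  MMEJ of deletions     6.9%

Trace decomposition
  total edited          30.0%  (R^2 1.0000)
  HR / NHEJ of edited   66.7% / 33.3%

Focus dynamics
  outside at 10 min     62.0%  (n=2000)
  accumulation          19.2%

ChIP-qPCR
  percent change        17.8%  (p=0.0235, n=13)

ROI enrichment
  mean DSB/domain ratio 0.887  (drop 11.3%)
```

Reading the numbers: the classifier recovers the generating pathway mix
(20.1% HR against a true 20%); 6.9% of pure-deletion products carry ≥ 2 bp
microhomology; the noise-free demo trace (70% unedited, 20% HR, 10% 1-bp
deletion) decomposes exactly, so 30% of molecules are edited and two thirds
of the edits are HR; 62% of simulated foci have left the polycomb body ten
minutes after appearing; and the ChIP arm estimates a 17.8% H3K27me3 loss
against a true 28% under 0.2-cycle well noise — the per-replicate spread is
what the paired t-test works against. Identical configurations reproduce
this report byte for byte; every stage's seed is in `run1/report.json`.

The same stages are available as library calls (`drwhite.sample_events`,
`call_junction`, `summarize`, `decompose`, `fraction_outside_at`,
`ddct_enrichment`, ...) and as per-stage subcommands (`drwhite simulate`,
`call`, `classify`, `decompose`, `dynamics`, `chip`, `expression`,
`validate`).

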