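# Methods

This note documents the models behind `drwhite`: what each simulator
emulates, the analysis conventions, the defaults and why, and what the
package's passing tests do and do not establish about real data.

## Reporter model and coordinates

The amplicon is assembled as `left_primer + left_arm + left_flank +
right_flank + right_arm + revcomp(right_primer)`, with the published
target-site flanks (`TTGAGCTGTAGGGATAA` / `CAGGGTAATAGCTCTTTG`) and primers
(`GACTGGACTCATTTACCGCCC` / `TTGGTAGGACACTGGGCAC`). The last 9 nt of the
left flank and first 9 nt of the right flank form the 18-bp I-SceI
recognition site. All coordinates are 0-based half-open; the cut is the
inter-base index at the flank boundary. The staggered 4-nt overhang of
I-SceI cleavage is not modelled: the package simulates repair *products*,
not cleavage chemistry.

The HR product is "the reporter minus the recognition site", observed as a
23-nt deletion. Any placement of that window containing the cut is
consistent with the readout; we fix `[cut−9, cut+14)`, which keeps the full
18-nt recognition site inside the deleted window. The classifier matches HR
by shift-equivalence (below), so products equivalent to this window under
junction ambiguity are HR regardless of the alignment convention used to
write them down.

Arms are drawn uniformly over A/C/G/T and resampled (up to 100 times) if
they recreate a flank or a second recognition site, so the cut coordinate
is always well defined. Arms must be ≥ 30 bp: read anchoring needs 12-bp
anchors placed 18 bp outside the flanks on each side. Anchors deliberately
sit *outside* the HR window — the published target-site flanks compose the
I-SceI site itself, which HR deletes, so anchoring on them would make HR
products unalignable; here they define only the cut coordinate.

## Microhomology and junction calling

For a deletion `[s, e)`, microhomology is defined as the junction ambiguity:
the number of distinct placements of an equal-sized deletion producing the
identical repaired sequence, minus one. At the left-aligned placement this
equals the largest `m` with `ref[s:s+m] == ref[e:e+m]`, allowing the
comparison to run past `e` (a deletion of one unit of a tandem repeat has
microhomology larger than the deletion itself). This is the standard MMEJ
convention and is placement-invariant; insertions are assigned
microhomology 0.

Calling uses longest-common-prefix/suffix arithmetic on the inter-anchor
segment. With raw prefix length `L` and suffix length `S` against a
reference segment of length `R` and read segment of length `M`:

- `M == R`, identical → unmodified; ≤ 2 scattered mismatches → unmodified
  (sequencing substitutions); one contiguous mismatch run →
  deletion-with-insert; otherwise unalignable.
- `M < R`, `L + S ≥ M` → pure deletion of `d = R − M`; valid start
  placements are `[R−S−d, L]`, so the left-aligned start is `max(0, R−S−d)`
  and the microhomology `min(L, R−d) − max(0, R−S−d)`.
- `M > R`, `L + S ≥ R` → pure insertion, with the analogous point range.
- Otherwise → deletion-with-insert (`[L, R−S)` replaced by the read run).

Distance to the cut uses the union of all equivalent placements ("the
equivalence region"): 0 when the region contains or touches the cut index,
else the gap in bases. This makes the ≤ 10 bp proximity filter indifferent
to left- versus nearest-placement alignment conventions; the convention is
recorded in output metadata.

## Pathway classification

Order of precedence on retained calls: (1) the HR signature — a pure 23-bp
deletion whose equivalence class contains the HR window — is HR
unconditionally, even if its junction shows ≥ 2 bp microhomology (the −23
product is the assay's HR readout; a spontaneous NHEJ deletion identical to
it is indistinguishable by construction and counted as HR, the assay's
known ambiguity); (2) indels above 25 bp are tallied as "other", kept out
of the repaired set but never silently dropped; (3) pure deletions with
microhomology ≥ 2 are MMEJ; (4) everything else — insertions, low-
microhomology deletions, deletions-with-insert regardless of microhomology
— is NHEJ. The 25-bp cap is applied to MMEJ as well as NHEJ, consistent
with the generator, which draws MMEJ sizes from the same ≤ 25 bp
distribution. Summary percentages use the assay's denominators: repaired
products over retained reads; HR/NHEJ over repaired products; MMEJ over
pure-deletion products.

## Event generator

Default mixture: HR 0.20, NHEJ 0.75, MMEJ 0.05 of products — inside the
reporter's published ranges (HR 17–26%, NHEJ 74–83%; MMEJ ≈ 6% of deletion
products, inside the published 3–9%). Within NHEJ, 99.3% of products
contain a deletion (0.5% as deletion-with-insert), matching the published
99.0–99.4% deletion-containing fraction. Deletion sizes are geometric-like
with P(1 bp) = 0.6 truncated at 25 bp (published spectra give only summary
ranges; 1-bp deletions dominate); insertions are 1–3 bp. NHEJ deletions are
rejection-sampled to junction microhomology ≤ 1 and never HR-equivalent;
MMEJ deletions are drawn from the enumerated set of cut-touching intervals
with microhomology ≥ 2 in the realized reference. Deletion-with-insert
events carry an insert that cannot extend either flank match and whose
length differs from the deletion's — an equal-length replacement is
observationally a substitution, not an indel product, and would be
unrecoverable by any caller.

Reads default to one full-length molecule per event (emulating merged
150-bp paired-end amplicon pairs; merging itself is out of scope), constant
Q30, independent per-base substitution errors; indel sequencing errors are
not modelled because the assay's signal is itself an indel. All generators
are pure functions of (parameters, seed) and refuse to run without a seed.

## Trace model and decomposition

The trace is indexed by sequencing position downstream of the cut: a
molecule with a net deletion of `d` bases upstream shows the reference base
shifted by `+d` at every position; an insertion shows ambiguity-averaged
signal (0.25 per channel) over the inserted stretch, then the reference
shifted by `−d` — inserted bases are unknown a priori, hence the uniform
channel model. The −23 candidate is therefore exactly the HR product's
downstream profile. Decomposition is nonnegative least squares over offsets
−25..+25 (window matching the 25-bp indel cap); weights below 0.1% are
zeroed and the rest renormalized, which also makes the spectrum report
invariant to uniform trace scaling. No per-component significance test is
attempted. R² is computed from the raw fit about the signal mean. Default
trace length is 50 positions (clamped so deletion candidates stay inside
the amplicon).

## Focus-track model

Tracks start inside a polycomb body at t = 0 on a 5-minute grid (imaging
interval 5–10 min in the emulated experiments; the query lag snaps to the
nearest sampled timepoint). The location at the 10-minute checkpoint is an
explicit categorical draw — presets `mu2_isceI_control` (60% outside),
`atrip_control` (77%), `atrip_dUtx` (53%) encode the published movement
percentages with a not-detectable fraction of 0, sidestepping the
denominator ambiguity; the summary nevertheless reports both denominators
(all foci, and detected-only). Foci inside at 10 min either exit later
(per-interval probability 0.4 from 15 min) or accumulate — never leave
before resolving — with accumulating fractions 0.21 / 0.33 for the ATRIP
presets (published) and 0.20 for Mu2 (chosen; not published). Resolution is
geometric on the grid starting after the checkpoint, with the hazard
calibrated so the median lifetime is 55 min (inside the published
30–80 min range); late exiters start their resolution clock after exiting,
shifting the realized median slightly upward but keeping it inside the
range. The default observation horizon is 45 min, as in the emulated
tracking experiments; since that is shorter than the median lifetime, the
median-resolution statistic is flagged undefined at the default horizon
and kinetics analyses should pass a longer `horizon_min` (the tests use
150 min).

## qPCR and ROI models

Each well's cycle threshold is `Ct = base_ct − log2(quantity) +
N(0, σ_Ct)`, independently per well, with `base_ct` = 22. Enrichment is
IP/input = `2^(Ct_input − Ct_IP)` normalized to an internal-control locus
(e.g. H3K27me3 at the target versus the *ubx* gene); no input-dilution
correction is applied since only ratios of ratios are interpreted and any
constant factor cancels (raw intermediates are convention-dependent). The
"ratio paired t-test" is a two-sided paired t-test on natural-log ratios —
the standard reading of that phrase — with Welch's t-test as the unpaired
variant; degenerate zero-variance inputs return p = 1 (no difference) or
p = 0 (constant nonzero log-difference) rather than NaN. A note on power:
with independent 0.2-cycle noise on all four wells behind each normalized
enrichment, the paired design at n = 13 has analytic two-sided power ≈ 0.79
at a true 28% loss — a property of this noise model worth knowing when
choosing replicate counts.

Spike-in panels emulate barcoded modified nucleosomes: specificity is each
mark's IP/input recovery as a percentage of the on-target mark's; marks
lacking a channel are reported absent rather than zero. The chi-square
helper is Pearson's test without continuity correction, pooling zero-margin
categories and warning when expected cells fall below 1.

ROI tables emulate per-cell mean intensities of a histone-mark reporter at
the DSB versus the whole polycomb body: `dsb = ratio × domain × noise` with
lognormal domain intensities (σ = 0.3 around 100 a.u.) and mean-one
lognormal ratio noise (σ = 0.10), so the expected per-cell ratio equals the
preset's true ratio — 0.90 for `damaged_control` (a ~10% drop) and 1.00 for
`damaged_dUtx` (no drop when the demethylase is depleted).

## What passing tests show — and do not

The suite establishes internal correctness: oracle equivalence of the
microhomology definition, exact recovery of noise-free decompositions,
≥ 99% truth-label recovery on zero-error reads, parameter recovery of the
movement/ROI/enrichment presets within sampling error, and determinism of
every generator under fixed seeds. Because the generators are calibrated to
published summary statistics rather than raw data, passing tests show that
the analysis recovers what the simulators encode — they do not validate the
biological models themselves, PCR amplification bias, chromatin structure,
cleavage kinetics, cell-cycle effects, or the behaviour of the released
TIDE/SIQ software beyond the conventions stated here.

## Problem sizes

Defaults used by the test suite and the reproduction script: 2000–5000
reads per classification experiment, 2000 tracks per movement preset, 300
cells per ROI preset, 13 qPCR replicates, 200 simulations for power
estimates. These sizes put binomial sampling error well below the effect
sizes of interest (e.g. ±1.1 percentage points SE on a 60% movement
fraction at n = 2000) while keeping any run in seconds.
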