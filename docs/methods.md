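# Methods

This note records the models, parameter choices and known limitations
behind `aqp-profiler`, in the order the pipeline runs.

## Physicochemical profile

**Molecular weight** is the sum of average (not monoisotopic) residue
masses plus one water (18.015 Da), reported in kDa, with the N-terminal
Met retained. This reproduces the ProtParam-style values family surveys
print. Ambiguous residues (X) have no defined mass and are rejected
rather than guessed.

**Net charge and pI.** The net charge at a given pH is the
Henderson–Hasselbalch sum over the two termini and the ionizable side
chains (D, E, C, Y negative; H, K, R positive). The default pK set is the
Bjellqvist/ExPASy table, including its residue-specific N-terminal pKs
(A, M, S, P, T, V, E) and C-terminal overrides for D/E; the EMBOSS set is
available via `pk_set="emboss"`. Because the charge is continuous and
strictly decreasing in pH, the pI is the unique root on [0, 14]; it is
found by bisection to a pH tolerance of 1e-10 (so the residual charge is
below 1e-6 even for short peptides) and conventionally rounded to two
decimals in reports. The test suite checks the bisection against a
0.001-step grid scan of |charge| and against Biopython's independent
Bjellqvist implementation.

**Transmembrane segments** come from Kyte–Doolittle hydropathy averaged
over a sliding window. Defaults: window 19 residues, threshold 1.6,
merge-gap 4, segment length bounds 15–30 residues — standard settings
for TM helices. Maximal runs of window centers above the threshold become
segments; nearby runs merge, short runs are dropped, over-long runs are
trimmed symmetrically around their hydropathy peak. This is a
hydropathy-only segmenter: it predicts no in/out topology and no signal
peptides, and counts other than six on real proteins should be read as a
flag for manual inspection, not a verdict.

## Anchored feature extraction

The package's central procedure projects annotated feature positions from
a *function-known anchor* onto each query:

1. Globally align the query to every anchor (Needleman–Wunsch with affine
   gaps; BLOSUM62, gap open 10, gap extend 0.5 — a gap of length L costs
   `10 + 0.5·(L−1)`). Traceback ties break in the fixed order diagonal,
   up, left, so alignments are reproducible. The implementation is a
   three-state Gotoh DP; its scores are verified against exhaustive path
   enumeration (short pairs) and Biopython's `PairwiseAligner`.
2. Take the best-scoring anchor (ties keep table order).
3. Carry each of the anchor's 20 annotated positions (NPA_LB, NPA_LE,
   ar/R H2/H5/LE1/LE2, Froger P1–P5, SDP1–9) through the alignment
   columns to the query. A position falling in a query gap is reported
   *unresolved* (sentinel `-`), never imputed.

Pairwise anchoring replaces the multiple alignment a manual survey would
use. For well-conserved families the best pairwise anchor and an MSA
column projection agree; the pairwise form is deterministic and testable
against planted truth. A star-MSA mode is deliberately out of scope.

NPA motifs are additionally located de novo: with exactly six predicted
TM helices, the loop-B candidate is the first N-P-X strictly between TM2
and TM3 and the loop-E candidate the first between TM5 and TM6. When the
TM count is not six the anchor projection is trusted; when both routes
exist and disagree, the projection wins and the discrepancy is logged as
a warning.

## Subfamily classification and naming

Distances are 1 − (fractional identity over aligned non-gap columns) from
the same global alignments; a Poisson correction (−ln identity) is
available but not default, since family surveys seldom state a model.
Trees come from Saitou–Nei neighbor joining (Q-criterion, standard branch
length formulas, negative lengths clamped to zero, deterministic
tie-breaking); the implementation is property-tested to recover the
generating topology of any additive matrix up to eight taxa and is
cross-checked against scikit-bio's NJ.

Queries inherit the subfamily and class of their nearest reference; the
reported *support* is the distance margin to the nearest reference of any
other subfamily. This nearest-reference rule substitutes for reading
clades off a drawn tree and is equivalent whenever subfamilies separate
cleanly, which the synthetic panel guarantees and real panels should be
checked for (low support = ambiguous placement). Proposed names follow
`<prefix><class>;<index>`: the nearest reference's index if unused,
otherwise the smallest unused positive integer in that class, so a batch
of queries always receives distinct names.

Bootstrap resampling of alignment columns is available in principle but
deliberately not part of the shipped surface; the distance margin plays
the support role here.

## Substrate rules

The six per-substrate SDP patterns (nine allowed-residue sets each) ship
as a data file transcribed from the published family survey, alongside
the survey's per-protein SDP observation table used as a fixture. A
9-residue string with zero mismatches is a *member*, with exactly one a
*member_novel* (the survey's "novel site" reading — single substitutions
in otherwise matching strings are reported as novel transporter types,
and no printed row carries two mismatches), with two or more a
*non_member*. `max_novel` is configurable. Unresolved positions count as
mismatches but are reported separately so a gap never silently passes as
a novel residue. The ar/R and Froger residues are reported descriptively
(e.g., the water-type F-H-T-R filter of PIPs) but do not enter substrate
calls, which rest on SDPs alone.

Note the package models one SDP 9-tuple per protein (one position set per
anchor), while the published per-substrate blocks use substrate-specific
position sets; feeding printed residue strings directly to the rule
engine is exact, whereas extraction-based substrate calls share one
position set across substrates.

## Expression quantification

Organ-level abundance uses ΔCt oriented as `Ct(reference) − Ct(gene)` and
reports `2^ΔCt`, so larger means more abundant — matching the convention
of heatmaps "normalized to actin". Stress responses use the classical
`2^−ΔΔCt` against a control sample. Technical replicates are averaged
within each biological replicate before any statistic (the nesting most
qPCR designs intend, though rarely state). Both statistics are invariant
to constant Ct shifts by construction, and the simulator round-trip shows
fold recovery unbiased within ±0.1 log₂ units at Ct noise of 0.2 cycles.

## Osmotic water permeability

Oocyte volumes derive from measured cross-sectional areas under a
spherical model (`r = √(area/π)`). Pf follows

    Pf = V₀ · [d(V/V₀)/dt] / (S₀ · V_w · (Osm_in − Osm_out)),

with V_w = 18 cm³ mol⁻¹ and the initial slope estimated over the first
10 minutes (configurable). With areas in cm², times in minutes (converted
to seconds internally) and osmolalities in mol cm⁻³, Pf is in cm s⁻¹.

**Slope estimator.** Under the spherical model the relative volume grows
as `(1 + kt/3)³`, so a straight-line fit of V/V₀ over a 10-minute window
overestimates the initial slope by roughly `kT/3` — more than 10% at
realistic gradients for a strongly expressing oocyte. The default
estimator therefore fits `(V/V₀)^{1/3}`, which the model makes exactly
linear, and recovers `d(V/V₀)/dt|₀` without curvature bias; the literal
linear fit remains available as `method="linear"`. Pf is computed per
oocyte and aggregated afterwards (per-oocyte fits, not pooled means), so
group statistics see true biological replication.

Group comparison is one-way ANOVA plus Fisher LSD pairwise t-tests using
the pooled within-group mean square — the classical pairing for oocyte
assays — with fold changes quoted against the water-injected control.

## Synthetic data

Generators are pure functions of their seeds and mirror each consumer's
preconditions. Proteins are 250 residues with six 25-residue TM segments
(each a shuffled, balanced I/L/V/F multiset — balanced so every planted
helix clears the hydropathy threshold at any seed) separated by
hydrophilic loops drawn uniformly from S/T/Q/G/E/D/K/R/H/Y; proline and
asparagine are excluded from loop backgrounds so the planted motifs are
the only N-P-X occurrences, and alanine is excluded to keep loop
hydropathy clearly sub-threshold. Features are planted at fixed
layout-consistent positions with family-typical residues per subfamily
(e.g., F-H-T-R + Q-S-A-F-W for PIPs). Anchors of a subfamily share a
background; classes diverge at 8% of non-feature positions; queries
replay their class's divergence and add flank mutations at a configurable
rate, with planted features always written last. Inter-subfamily
distances therefore exceed intra-subfamily ones by construction.

The swelling simulator integrates the same spherical ODE the estimator
assumes (forward Euler, 0.5 s steps by default; halving the step changes
recovered Pf by <0.5%), with defaults emulating a 1.3 mm oocyte in a
5-fold diluted bath (160 mOsm gradient) sampled every 30 s for 10 min and
optional Gaussian area noise. Ct tables place genes at
`ref_ct − log₂(abundance)` with Gaussian biological (sd = noise_sd) and
technical (sd = noise_sd/2) noise, 3×3 replicates by default. Additive
distance fixtures are random binary trees with U(0.1, 1) branch lengths.

**What passing synthetic tests does not show:** the generators use
uniform background composition, mutation without indels, exactly
spherical oocytes and Gaussian noise. Real sequences carry insertions and
deletions that exercise the unresolved-feature path far more often;
real oocytes deviate from sphericity and their noise is not area-additive
Gaussian. Results on synthetic data bound the method's correctness, not
its robustness to every property of real data.

## Problem sizes

The shipped test suite and the acceptance script use 100 planted queries
for feature recovery, 200 random sequences for the pI oracle, 50 random
4–5-taxon matrices for the NJ oracle, short pairs (≤8 residues) for
exhaustive alignment enumeration, 6 oocytes per group for the Pf
comparison, and 200 replicate Ct tables for fold-recovery bias — sizes at
which every stochastic check is stable across seeds while the whole suite
runs in seconds to minutes.

## Known limitations

- The bundled default anchor panel is synthetic; real-data classification
  quality depends on the curated panel a user supplies, and which natural
  anchor annotates each feature is a curation decision this package does
  not make.
- Hydropathy-only TM prediction has no topology or signal-peptide
  awareness.
- One SDP position set per anchor (see above).
- Nearest-reference classification can misassign chimeric or deeply
  divergent sequences; inspect the support margin and the NJ tree.
- No genome-scale candidate search (HMM/BLAST) and no motif discovery;
  the package starts from candidate protein sequences.
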