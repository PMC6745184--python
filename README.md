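# aqp-profiler

Aquaporins (AQPs, major intrinsic proteins) are channel proteins with a
strongly conserved architecture — six transmembrane helices, two N-P-A
motifs in loops B and E, an aromatic/arginine (ar/R) selectivity filter —
whose residue-level variation determines which substrates beyond water
(ammonia, boric acid, CO₂, H₂O₂, silicic acid, urea) a given channel can
pass. Plant genome surveys of this family all follow the same recipe:
compute physicochemical properties per protein, locate the NPA motifs,
read the ar/R filter, Froger's positions (P1–P5) and the nine
specificity-determining positions (SDPs) off an alignment with
function-known reference AQPs, classify members into the PIP/TIP/NIP/SIP
subfamilies by distance-based phylogenetics, and back functional claims
with qPCR expression profiling and *Xenopus* oocyte swelling assays.

`aqp-profiler` packages that recipe as a tested, reproducible library and
CLI for family-survey authors and reviewers:

- **seqio** — FASTA, reference-anchor tables (TSV), exon tables
  (GFF3/TSV); all coordinates 1-based.
- **physchem** — length, average-mass MW, Bjellqvist/EMBOSS pI by
  bisection of the Henderson–Hasselbalch net charge, Kyte–Doolittle
  hydropathy TM segmentation.
- **features** — affine-gap Needleman–Wunsch (BLOSUM62), best-anchor
  selection, projection of the 20 annotated feature positions onto
  queries, de novo N-P-X scans cross-checking the projection.
- **phylo** — 1 − identity distances, Saitou–Nei neighbor joining
  (Newick/PHYLIP output), nearest-reference subfamily calls and
  `EsPIP1;4`-style nomenclature.
- **substrates** — the six published per-substrate SDP patterns as a rule
  engine: 0 mismatches → member, 1 → novel-site member, ≥2 → non-member.
- **quant** — 2^ΔCt / 2^−ΔΔCt expression with replicate nesting, and
  osmotic water permeability `Pf = V₀·[d(V/V₀)/dt] / (S₀·V_w·ΔOsm)` from
  oocyte swelling series, with one-way ANOVA + LSD group comparison.
- **synthetic** — ground-truth generators for all of the above (planted
  features, tree metrics, Ct tables, swelling curves).

## Worked example

```python
from aqp_profiler.datasets import default_anchor_panel
from aqp_profiler.features import extract_feature_profile
from aqp_profiler.physchem import physchem_profile
from aqp_profiler.substrates import builtin_patterns, match_sdp
from aqp_profiler.synthetic import PlantSpec, make_query

panel = default_anchor_panel()                 # bundled synthetic panel
query, truth = make_query(PlantSpec(subfamily="TIP", class_label="TIP2",
                                    flank_mutation_rate=0.05, seed=1))

phys = physchem_profile(query)
prof = extract_feature_profile(query, panel)
ammonia = next(p for p in builtin_patterns() if p.substrate == "ammonia")
call = match_sdp(prof.sdp, ammonia)
print(phys.length_aa, phys.tm_count, round(phys.mw_kda, 2), phys.pi)
print(prof.npa_lb, prof.npa_le, prof.arr, call.status)
```

prints

```
250 6 28.95 8.85
NPA NPA ('H', 'I', 'G', 'R') member
```

i.e., a 250-residue protein with the six expected TM helices, MW 28.95 kDa,
pI 8.85, canonical NPA motifs in loops B and E, the TIP2-typical H-I-G-R
ar/R filter, and an SDP string matching the ammonia-transporter pattern —
exactly the planted truth.

The same pipeline runs from the shell:

```bash
aqp-profiler simulate --out-dir demo --seed 3 --n-queries 6
aqp-profiler annotate demo/queries.fasta --anchors demo/anchor_panel.tsv --out-dir demo
aqp-profiler classify demo/queries.fasta --anchors demo/anchor_panel.tsv --out-dir demo
aqp-profiler substrate demo/queries.fasta --anchors demo/anchor_panel.tsv --out-dir demo
aqp-profiler expression demo/ct_table.csv --reference-gene actin --mode ddct \
    --control-sample control --log2 --out-dir demo
aqp-profiler pf demo/swelling.csv --osm-in 2e-4 --osm-out 0.4e-4 --out-dir demo
```

## File formats

The anchor table is tab-separated with header
`id subfamily class NPA_LB NPA_LE H2 H5 LE1 LE2 P1..P5 SDP1..SDP9 sequence`;
positions are 1-based on the anchor's own sequence, and NPA positions point
at the motif's first residue. Ct tables are CSV with columns
`gene,sample,bio_rep,tech_rep,ct`; swelling series are CSV with
`oocyte_id,group,time_min,area`. The bundled default anchor panel is
synthetic (generated, with planted features); swap in a curated table of
natural anchor AQPs for real-data work.

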