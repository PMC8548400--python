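# degradomics

Analysis toolkit for **proteasome degradation-product peptidomics**: the
non-tryptic peptides released when a 20S core particle or a 26S holoenzyme
digests a substrate, identified by LC-MS/MS and reported as peptide tables
with PSM ("MS/MS") counts.

The 20S and 26S proteasomes share their catalytic sites, so telling their
intracellular contributions apart requires comparing *product signatures*
rather than activities: which peptide bonds each complex prefers to cut,
how long its products run, how diverse its product repertoire is, and
whether products carry ubiquitin-derived isopeptide remnants (evidence that
the conjugated ubiquitin tag itself was proteolyzed).  This package
implements that comparison for anyone profiling proteasome (or other
processive protease) products against a known substrate sequence — plus a
synthetic digestion simulator that stands in for raw MS data in tests.

## The statistics at the core

Peptides are mapped exactly onto the substrate; a product spanning residues
`start..end` evidences cleavages at bonds `start-1` and `end` (P1 = the
residue N-terminal to a cut bond).  PSM counts of all products bounded by a
site are integrated per condition, and the **relative cleavage preference**
of enzyme A over enzyme B at each P1 position is

```
log2( (n_A or 0.1) / (n_B or 0.1) )
```

with zero counts replaced by the pseudo-value 0.1 and a two-fold ratio
flagging a preferred site.  Sites unobserved in both conditions are NA, not
zero.  Around used sites, P4–P4′ residue frequencies weighted by site usage
give Schneider–Stephens information-content logos
(`IC = log2 20 − H`, letter height `f × IC`) and a chi-square differential
comparison between enzymes.  Supporting analyses: the CPM-normalized,
per-peptide max-rescaled sample × peptide occupancy matrix (samples < 50
PSMs and single-sample peptides dropped) with classical-MDS ordination and
Ward clustering; boxplot-convention product-length summaries with
Mann–Whitney / Welch tests; Shannon-entropy product diversity; ubiquitin
C-terminal remnant (GG/RGG/LRGG) enumeration, masses, and branched-peptide
validation against anchor lysines; and per-protein mean disorder scores
from IUPRED-style tracks.

## Worked example

Two enzymes digest the packaged 88-residue cyclin B1 N-terminal fixture: a
"20S-like" model with six-fold elevated cleavage at sites 42, 50 and 64 and
a 7–35 aa product window, and a "26S-like" model with uniform weights and a
7–25 aa window.

```python
import numpy as np
import degradomics as dg

cyclin = dg.cyclin_b1_nt()
weights = np.ones(len(cyclin) - 1)
fast = weights.copy(); fast[[41, 49, 63]] = 6.0
m20 = dg.DigestionModel(cyclin.id, fast, length_min=7, length_max=35, depth=5000, seed=1)
m26 = dg.DigestionModel(cyclin.id, weights, length_min=7, length_max=25, depth=5000, seed=101)

table, truth = dg.simulate_two_condition(m20, m26, cyclin)
table = dg.filter_replicates(table, 2)            # 2-of-3 replicate filter
mapped, _ = dg.map_table(table, cyclin)
pref = dg.compute_preference(
    dg.integrate_site_counts(mapped, "20S"),
    dg.integrate_site_counts(mapped, "26S"),
)
print(pref.sort_values("log2_ratio", ascending=False).head(3).to_string(index=False))
```

```
 site  value_a  value_b  log2_ratio     call
   42   2059.0    386.0    2.415271 prefer_a
   50   2136.0    427.0    2.322604 prefer_a
   64   1764.0    381.0    2.210988 prefer_a
```

The three planted sites surface with `log2_ratio > 1` (more than two-fold),
so they are called `prefer_a` — the 20S-like enzyme.  The length signature
and the remnant table follow the same pattern:

```python
x = dg.peptide_lengths(table, "20S"); y = dg.peptide_lengths(table, "26S")
u, p = dg.mann_whitney_u(x, y)
# median product length: 20S 19 aa vs 26S 15 aa (Mann-Whitney p = 9.42e-47)

for r in dg.enumerate_remnants(dg.ubiquitin(), 2, 4):
    print(f"{r.paper_notation:<5} -> +{r.mono_mass:.5f} Da on K")
# GG    -> +114.04292 Da on K
# GGR   -> +270.14403 Da on K
# GGRL  -> +383.22809 Da on K
```

A branched peptide such as `ARLPLPKE` with a `GGR` remnant validates
against the K64-only construct fixture with
`dg.annotate_branched_peptide(...)`, which localizes the branch to the K64
anchor.

The same analyses run from the shell: `degradomics run --config run.yaml
--out DIR`, with standalone subcommands `simulate`, `map`, `p1`,
`lengths`, `remnants`.  Every output TSV carries the configuration as
`#`-comment headers and references the run manifest.

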