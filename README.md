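# epimsap

Analysis of **MSAP** (Methylation-Sensitive Amplification Polymorphism)
fingerprints, built for studies that ask whether in vitro propagation (or any
two-group contrast) induces genetic and/or epigenetic somaclonal variation in
clonally propagated plants.

MSAP profiles a genome's CCGG sites with two isoschizomers that share the
recognition sequence but differ in methylation sensitivity: *Hpa*II and
*Msp*I. Each sample × locus cell therefore carries a pair of binary band
calls, and the four combinations map onto cytosine-methylation states:

| HpaII | MspI | Type | Interpretation |
|-------|------|------|----------------|
| 1 | 1 | I   | unmethylated |
| 0 | 1 | II  | internal-cytosine methylation |
| 1 | 0 | III | hemimethylation of the outer cytosine |
| 0 | 0 | IV  | fully methylated (or site absent) |

From there the package implements the complete downstream analysis:

- **Locus partition** into Methylation-Susceptible Loci (MSL: enzyme
  discordance above a scoring-error threshold; epigenetic signal) and
  Non-Methylated Loci (NML: concordant presence/absence; genetic signal).
- **Diversity**: per-locus Shannon index
  S = −(f ln f + (1−f) ln(1−f)) for dominant markers, with
  Wilcoxon rank-sum and paired-t comparisons.
- **AMOVA**: two-level analysis of molecular variance on squared pairwise
  distances, Φ_PT (band matrices) and Φ_ST (MSL/NML recodes), with
  permutation p-values (9,999 relabellings by default, add-one estimator).
- **Ordination**: PCoA (Gower double-centering) and PCA.
- **Differential methylation**: per-MSL Freeman–Halton exact test on the
  2 × k group × state table, Benjamini–Hochberg FDR across each
  genotype × primer family.
- **Clustering**: UPGMA on Gower distances with deterministic tie-breaking,
  Newick export, and categorical Type I–IV heatmaps.
- **Synthetic studies**: a ground-truth generator emulating a
  3-genotype × (field vs micropropagated) × 24-ramet design with ~240 loci
  per primer combination, a realistic state mixture, seeded differential
  loci and per-cell scoring error — so every stage is testable end to end.

## Worked example

```python
import epimsap as em

sim = em.simulate(em.SimConfig(n_genotypes=1, n_per_group=24, n_loci=240,
                               dm_fraction=0.15, dm_effect=0.6,
                               error_rate=0.0, primers=("E",), seed=3))
profile = sim.profiles["E"]
groups = {r.sample_id: r.propagation for r in sim.metadata}
states = em.call_states(profile)
part = em.partition_loci(states, error_rate=0.05)

for label, matrix in (
    ("PhiPT (HpaII bands)", profile.hpa.values),
    ("PhiST (MSL recode)", em.recode_msl_binary(states, part)),
    ("PhiST (NML recode)", em.recode_nml_binary(profile, part)),
):
    D = em.pairwise_distance(matrix, "hamming_sq")
    res = em.amova_two_group(D, groups, n_perm=9999, seed=30)
    print(f"{label}: Phi = {res.phi:.3f}, p = {res.p_value:.4f}")
```

prints

```
PhiPT (HpaII bands): Phi = 0.046, p = 0.0001
PhiST (MSL recode): Phi = 0.056, p = 0.0001
PhiST (NML recode): Phi = 0.005, p = 0.2764
```

Φ is the among-group fraction of molecular variance: the band-level
differentiation between propagation systems (Φ_PT = 0.046) is carried almost
entirely by the methylation-susceptible loci (Φ_ST = 0.056, p = 0.0001)
rather than by the genetic NML fraction (Φ_ST = 0.005, n.s.) — the signature
of epigenetic somaclonal variation. The `examples/` directory has one short
script per capability (state calling, primer QC, AMOVA/ordination,
differential methylation, full pipeline), and the `epimsap` command exposes
`simulate`, `qc`, `run --config config.yaml` and `report` for shell use.

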