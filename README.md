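# allodyn

Allosteric-site ranking in G protein-coupled receptors (GPCRs) from
correlations between inter-residue distance fluctuations and the
receptor's activation motion.

## The method

GPCR activation is dominated by a stereotyped geometry change: TM6
swings outward while TM3 and TM7 move inward. A single collective
variable captures it,

    Δ = d1 − d2

where d1 is the Cα–Cα distance between anchor residues on TM2 and TM6
and d2 the distance between anchors on TM3 and TM7. On the β2
adrenergic receptor, active structures show Δ > 8 Å while inactive
structures show negative Δ, so Δ separates conformational states of an
ensemble (experimental structures, normal-mode harmonic trajectories,
or MD frames).

For every residue pair (i, j) the coupling to activation is the Pearson
correlation, across the ensemble, of the Cα distance d_ij with Δ:

    c_ij = cov(d_ij, Δ) / (σ_dij · σ_Δ)

A candidate binding site S with N residues is scored by the mean
absolute coupling over its internal pairs,

    C_site = 2 / (N(N−1)) · Σ_{i<j∈S} |c_ij|

and sites are ranked by C_site. Sites above the mean of the ranking are
flagged as potentially allosteric: a pocket whose internal geometry
moves in lock-step with activation is a pocket whose occupation can
plausibly block or bias that activation.

The package covers the full workflow:

* **ensemble_io** — read PDB/mmCIF/trajectory ensembles, harmonise
  heterogeneous entries onto their common residues, Kabsch-superpose.
* **delta** — anchor presets (β2AR, GCGR, M2 muscarinic) or explicit
  anchors; per-frame Δ and state classification.
* **coupling** — the c_ij matrix, strong-coupling mask (|c| > 0.75),
  C_site scores and the ranked site table.
* **sites** — parse fpocket/MDpocket dummy-atom output, retain pockets
  present in ≥ 40 % of frames, assign residues within 4.0 Å of the
  dummy atoms, filter orthosteric overlap.
* **harmonic** — Cα elastic-network normal modes and harmonic two-state
  ensembles (a coarse-grained stand-in for all-atom NMA trajectories).
* **synthetic_fixtures** — a toy 7-helix receptor with a planted
  coupled site and decoys, for end-to-end validation with known ground
  truth.
* **pipeline_cli** — the `allodyn` command (`run`, `delta`, `sites`,
  `rank`, `harmonic`, `synth`).

## Worked example

Generate a synthetic two-state ensemble (100 frames, 70 residues, one
planted coupled site, three decoys, 0.2 Å coordinate noise) and run the
full pipeline on it:

```bash
allodyn synth --frames 50 --noise 0.2 --seed 7 --out fixtures
cat > config.yaml <<EOF
ensemble_sources: [fixtures/ensemble.pdb]
delta_anchors: ['A:16', 'A:56', 'A:26', 'A:66']
site_lists: fixtures/sites.json
EOF
allodyn run --config config.yaml --out results
```

which prints:

```
allodyn run summary
===================

frames: 100   common residues: 70
Delta[inactive]: n=29 mean=-0.36 A range=[-0.81, -0.02]
Delta[intermediate]: n=48 mean=4.52 A range=[0.02, 8.00]
Delta[active]: n=23 mean=8.30 A range=[8.02, 8.74]
strong couplings (|c| > 0.75): 415 pairs

site ranking (mean C_site = 0.30):
   1. coupled      C_site=0.99 *   top pair A:38(ALA)--A:46(ALA) c=+0.99
   2. decoy2       C_site=0.08   top pair A:52(ALA)--A:59(ALA) c=-0.18
   3. decoy3       C_site=0.07   top pair A:24(ALA)--A:9(ALA) c=-0.14
   4. decoy1       C_site=0.05   top pair A:2(ALA)--A:5(ALA) c=+0.12

* C_site above the ranking mean (potentially allosteric)
```

The planted site is recovered at rank 1 with near-perfect coupling
(its internal distances were constructed to vary linearly with the
latent activation coordinate), while the decoy sites — which only see
isotropic noise — score an order of magnitude lower. The frames
labelled "intermediate" are active-state frames whose noisy Δ falls
just below the 8 Å reporting threshold; the threshold affects labels
only, never the coupling computation. `results/` additionally contains
the per-frame Δ table, the full and strong-masked coupling matrices,
per-site sub-matrices, the ranking as TSV/JSON, a PDB with C_site
written into B-factors, and the exact config used.

Ranking arithmetic can also be run directly on published C_site values:

```bash
allodyn rank --scores scores.json     # {"4": 0.76, "3": 0.61, ...}
```

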