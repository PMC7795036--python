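# Methods

## The model

The analysis treats a receptor's conformational ensemble as a sample of
its activation dynamics and asks which candidate binding pockets move
in concert with the activation transition.

**Activation variable.** Δ = d1 − d2, with d1 the Cα distance between
TM2 and TM6 anchors and d2 the TM3–TM7 anchor distance. The anchors are
receptor-specific; presets store the author residue numbers for the
β2 adrenergic receptor (Y70, G276, C125, I325), the glucagon receptor
(A175, L347, L243, V398) and the M2 muscarinic receptor (Y60, L390,
L115, C439). Other receptors need explicit anchors: resolving generic
GPCRdb numbering (e.g. "2x41") to author numbers requires an external
lookup service and is deliberately not implemented, keeping the package
free of network dependencies.

**Coupling.** c_ij is the Pearson correlation between the per-frame Cα
distance d_ij and Δ. Pearson is appropriate because both the anchor
motions and the site deformations of interest are monotone, roughly
linear functions of the activation coordinate; no significance testing
is attached since the ensembles are small and highly structured.

**Site score.** C_site is the mean of |c_ij| over the N(N−1)/2
unordered residue pairs inside a site. Using the absolute value makes
compressing and expanding pockets score alike. Sites are ranked by
C_site; the above-mean flag uses a strict comparison against the
unweighted arithmetic mean of the listed scores, computed on unrounded
values (scores are rounded to two decimals only in report tables).

## Assumptions

* Frames are exchangeable: each frame carries weight 1, and inactive
  and active conformations are pooled without per-state reweighting.
  (An optional frame-weight vector would be a natural extension; it is
  not currently exposed.)
* Residue identity across frames is (chain, author number, insertion
  code). Heterogeneous experimental entries must share author
  numbering; no sequence alignment is attempted. Mutated residues still
  harmonise because the residue name is not part of the identity.
* A residue missing its Cα in any frame is removed from the analysis
  globally (logged), rather than imputed per frame.
* Correlations need at least 3 frames and a non-constant Δ; both are
  enforced.

## Parameters and defaults

| parameter | default | unit | role |
|---|---|---|---|
| active Δ threshold | 8.0 | Å | state label "active" (reporting only) |
| inactive Δ threshold | 0.0 | Å | state label "inactive" (reporting only) |
| strong-coupling threshold | 0.75 | — | \|c\| mask for matrix reports (strict >) |
| pocket presence fraction | 0.40 | — | retain pockets present in ≥ 40 % of frames (inclusive) |
| residue-assignment cutoff | 4.0 | Å | residue joins a site if any heavy atom is within the cutoff (inclusive) of any dummy atom, in ≥ 1 frame |
| orthosteric overlap | 0.50 | — | drop a site when overlap reaches 50 % of the smaller set |
| ENM cutoff | 13.0 | Å | Cα spring network interaction range |
| ENM gamma | 1.0 | energy/Å² | uniform spring stiffness (sets the energy scale only) |
| harmonic modes | 100 | — | lowest internal modes combined per trajectory |

The Δ thresholds are empirical observations on the β2 adrenergic
receptor; they are configuration, not a claim of generality across
receptors, and they never enter the coupling computation.

## Numerical choices

* **Correlations** use a two-pass centered-moment formula with
  exactly-rounded frame sums (`math.fsum`). This makes the coupling
  matrix bitwise invariant under frame permutation and keeps ensemble
  self-concatenation within 1e-12. Each unordered pair is computed once
  and mirrored, so symmetry is exact.
* **Zero-variance pairs.** A distance that does not fluctuate has no
  defined correlation. Constancy is detected relative to machine
  epsilon at the series' own scale (the rounding of the mean otherwise
  manufactures ~1-ulp spurious variance). Invalid pairs are flagged,
  contribute 0 to C_site sums, and stay in the denominator: a rigid
  pair dilutes a site's score rather than inflating it.
* **Superposition** is Kabsch (SVD-based least squares) on common-
  residue Cα coordinates; degenerate (collinear or < 3 point) sets are
  rejected. Superposition is optional before coupling (distances are
  rigid-motion invariant) but required before pocket ingestion, which
  must share the detector's frame of reference.
* **Site assignment** uses a KD-tree per frame with the boundary made
  explicitly inclusive (distance equal to the cutoff counts), matching
  the inclusive reading of "within 4.0 Å"; tests verify exact set
  equality against an all-pairs scan.
* **Ranking ties** break by site label ascending; ranks are 1-based.
* **ENM zero modes** are eigenvalues below 1e-8 of the spectral
  maximum; a connected, non-collinear 3-D network yields exactly 6.

## The harmonic generator

The elastic network is a Cα-level anisotropic network model: springs of
uniform stiffness between all Cα pairs within the cutoff, Hessian
blocks −γ êê<sup>T</sup>. Harmonic trajectories displace the reference
along the lowest-frequency internal modes with independent Gaussian
amplitudes of variance temperature_scale/λ_k per mode (equipartition);
a deterministic sinusoidal sweep is available for visualisation-style
oscillation. Two-state ensembles concatenate trajectories generated
around an inactive and an active reference.

This is a known fidelity gap by design: an all-atom, force-field
normal-mode analysis sees chemistry (side chains, hydrogen bonds,
minimised geometry) that a Cα network cannot. The generator reproduces
the *structure* of the workflow — low-frequency collective fluctuation
around each state plus a between-state geometry change — not the
quantitative mode content of any particular force field. Published
per-receptor C_site values from all-atom NMA ensembles are therefore
not a target the harmonic module is expected to reproduce; its tests
check physics (zero modes, orthonormality, equipartition, mean
convergence), not table values. The amplitude convention of
mode-following trajectory writers is not standardised; equipartition
scaling was chosen as the statistically natural one.

## The synthetic benchmark

The toy receptor is an idealised Cα bundle: 7 helices of 10 residues on
a circular arrangement (helix radius 2.3 Å, rise 1.5 Å/residue, 100°
twist, bundle radius 11 Å). Per frame a latent activation coordinate
λ ∈ {0, 1} drives:

* the TM6 anchor outward along the TM2→TM6 axis and the TM7 anchor
  inward along the TM7→TM3 axis, split 3:1 so that Δ changes by exactly
  `activation_gap` (default 8 Å) between pure states — mirroring the
  dominant outward TM6 motion;
* the planted site's residues through a uniform scaling about their
  centroid, making every internal distance exactly linear in λ with
  mean slope `coupling_slope` (default 1 Å per Å of Δ);
* nothing else: decoy residues and the rest of the bundle receive only
  i.i.d. Gaussian coordinate noise (default σ = 0.2 Å), as do all
  residues.

Defaults are the benchmark's study conditions: 50 + 50 frames, 8 Å gap,
σ = 0.2 Å, slope 1. In the noiseless limit the coupled site's C_site is
exactly 1 and decoy correlations are undefined (zero variance); with
noise, recovery degrades monotonically, and at the default noise the
planted site ranks first in ≥ 95 % of seeds.

Collision handling: a clash (< 1 Å between residues) in the
deterministic deformed geometry is an error — it means the planted
motion itself is infeasible. Clashes introduced by the noise draw are
retried up to 10 times and then accepted with a warning, because the
i.i.d. jitter models coordinate uncertainty, not sterics; without this
distinction large-noise sweeps would be impossible to generate.

What the toy does **not** emulate: real secondary-structure geometry,
side chains, loops (notably the ICL2 disorder-to-helix transition that
matters in real receptors), membrane context, correlated elastic noise
(that role belongs to the harmonic module), or realistic pocket shapes.
Passing the benchmark shows the statistical machinery recovers a
planted linear coupling at realistic noise; it does not validate
predictions on real receptors, which depend on ensemble quality and
pocket curation.

## Pocket handling and curation

Pocket detection is external (fpocket/MDpocket); the package parses the
detector's STP dummy-atom PDB dialect (pocket index in the residue-
number field; single multi-MODEL file, per-frame files, or a static
single-model cloud). Surface-vs-buried disposition is not computed
automatically — that judgement is not operationalisable from the dummy
atoms alone — so curation is explicit: an orthosteric residue set
(overlap rule above), excluded labels, and per-site keep/drop flags.
Residue-list input bypasses detection entirely.

## Problem sizes

Tests and the acceptance script run on the toy receptor (70 residues,
100 frames; 100 seeds for the recovery benchmark), on random ensembles
of ≤ 8 residues × ≤ 25 frames for brute-force oracle equivalence, and
on 10⁴-frame harmonic trajectories for equipartition checks — sizes at
which the brute-force cross-checks remain exact and fast. The
implementation itself is vectorised and handles receptor-scale inputs
(hundreds of residues, thousands of frames).

## Known limitations

* Author-numbering harmonisation fails on ensembles with inconsistent
  numbering; no alignment fallback exists.
* Pooled-frame Pearson correlation conflates within-state and
  between-state variation; ensembles dominated by one state yield weak,
  noisy couplings.
* C_site has no significance calibration; rankings are relative within
  one ensemble, not comparable across receptors.
* The optional surface-accessibility heuristic for burial filtering is
  not implemented; burial curation is manual.
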