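# mandifem

Planar finite-element chewing biomechanics and geometric morphometrics
of mandibles, with phylogenetic comparative statistics and SVM-based
diet classification.

## The problem

Comparative studies of feeding adaptation ask whether a jaw is built to
comminute mechanically hard foods, and whether specimens of unknown
ecology (fossils) fall with the hard- or the soft-food eaters of a
comparative clade.  A widely used protocol answers this from lateral
2D mandible models: simulate biting with plane-stress finite elements,
summarise each jaw's strength by stress percentiles, describe its shape
by landmark morphometrics, account for phylogeny, and train a
classifier on the labeled species.  `mandifem` packages that whole
chain as a tested Python library — solver, mesher, load construction,
statistics and classifiers — together with a synthetic generator of
mandibles and phylogenies, so every stage is verifiable without access
to specimen photographs.

It is aimed at researchers in comparative biomechanics and evolutionary
morphometrics, and at anyone needing a self-contained, oracle-tested 2D
QUAD8 plane-stress solver with area-weighted stress statistics.

## The model in brief

* **Mechanics.** Each mandible is a thin plate of constant thickness t
  (mean of three corpus breadths), isotropic linear-elastic bone
  (E = 21 GPa, ν = 0.45), meshed with quasi-uniform 8-node
  quadrilaterals.  Four bite scenarios (incisive, canine, premolar,
  molar) fix the condyle fully and the bite point perpendicular to the
  occlusal plane; masseter, temporalis and pterygoid forces act along
  insertion→origin centroid directions in proportion to attachment
  areas.  Between specimens the total force is scaled
  quasi-homothetically, F = √(S/S_ref)·(t/t_ref) with the reference at
  1 N, so stress fields are size-free: σ ~ F/(l·t).
* **Strength summary.** Per scenario, the area-weighted percentiles
  M25, M50, M75, M95 of element von Mises stress
  σ_vM = √(σx² + σy² − σxσy + 3τxy²) — 16 variables per specimen.
  Hard/soft group differences are tested by pairwise PERMANOVA
  (Anderson's pseudo-F on Euclidean distances, Holm-corrected).
* **Shape.** Twelve homologous landmarks, generalized Procrustes
  superimposition, PCA; multivariate phylogenetic signal K_mult and the
  phylogenetic two-block PLS between shape and stress blocks, both
  under a Brownian-motion model via the phylogenetic covariance C.
* **Classification.** Linear-kernel SVMs on (a) Box-Cox-standardised
  stress percentiles and (b) the shape PCs covering ≥95% variance;
  cost tuned by leave-one-out CV with per-fold preprocessing; accuracy
  and Cohen's κ reported; Platt posteriors P(hard)/P(soft) for
  unlabeled specimens.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

`examples/04_full_pipeline.py` simulates 30 labeled extant specimens
plus 12 unlabeled fossils, runs the full chain and prints:

```
PERMANOVA H vs S on 16 stress percentiles: pseudo-F = 20.4, Holm p = 0.0010
Kmult (shape, all 42 tips) = 0.355, p = 0.0020
phylogenetic PLS shape vs stress: r = 0.903, p = 0.0010
4 PCs cover >=95% of shape variance
stress SVM:  LOOCV accuracy 0.967, kappa 0.933, cost 1.44
shape SVM:   LOOCV accuracy 0.933, kappa 0.867, cost 92.4
...
combined soft calls: 12/12
```

Reading this: mandibular stiffness separates the two diet classes
(PERMANOVA); shape carries significant but sub-Brownian phylogenetic
signal (K < 1 here because diet effect and noise overlay the tree
structure); shape and stress covary strongly after phylogenetic
correction; both classifiers recover the simulated diet effect almost
perfectly; and all 12 fossils — generated from the soft regime — are
assigned P(soft) > 0.5 when the two models' posteriors are averaged.

The other examples exercise single capabilities: dataset simulation and
file formats (`01`), meshing + one FE solve with VTK export (`02`), and
the morphometric/phylogenetic statistics alone (`03`).

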