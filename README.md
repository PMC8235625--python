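# callimorph

Phylogenetically informed 3D geometric morphometrics of limb long bones.

`callimorph` is built for comparative morphologists asking whether a
locomotor habit — here vertical clinging and leaping (VCL) versus
horizontal leaping (HL) in tamarins and marmosets — leaves a signature in
the shape, size, and evolutionary tempo of the humerus and femur. It
implements the full analysis chain as a tested, scriptable Python library:

- **Semilandmarks**: curve resampling to equal arc length, template-based
  patching of surface semilandmarks onto specimen meshes, and sliding under
  the minimum bending energy criterion (thin-plate spline, 3D kernel
  φ(r) = r), with the closed-form GLS solution
  t\* = −(UᵀBU)⁺UᵀB(y − x).
- **Superimposition**: full generalized Procrustes analysis (unit centroid
  size, proper rotations only) and species mean forms (consensus × mean CS).
- **Comparative statistics**: Blomberg's K and its multivariate
  generalization K_mult (permutation-tested), phylogenetic ANOVA with a
  Brownian simulation null, and sequential MANCOVA (Pillai's trace) of
  shape ~ log CS + locomotion + interaction on the PCs carrying 95% of
  variance.
- **Classification**: between-group PCA with cross-validated typicality
  reclassification (small-sample F transformation of Mahalanobis
  distances) and a permutation test on the distance between group means.
- **Evolutionary rates**: phylogenetic ridge regression
  β̂ = (XᵀX + λI)⁻¹Xᵀ(y − root) giving a rate vector per branch, and
  clade-wise shift detection by randomization.
- **Trees**: composite-phylogeny construction by cross-multiplied branch
  scaling, tip substitution, parsimony and stochastic-mapping ancestral
  reconstruction of the binary locomotor character.
- **Synthetic data**: a generator producing bone-like templates, Brownian
  species shapes with clade rate multipliers, group offsets, allometry and
  specimen noise — every stage is testable without downloading anything.

See `docs/methods.md` for models, defaults, and numerical choices.

## Worked example

```python
import numpy as np
import callimorph as cm

# simulate a study-sized dataset with a planted locomotor-group offset
recipe = cm.SimulationRecipe(seed=42, n_specimens_per_species=3)
dataset = cm.generate_dataset(recipe, with_meshes=False)
print(f"{len(dataset.configs)} specimens, {dataset.tree.n_tips} species")

# slide semilandmarks against the consensus, then superimpose
configs, trace = cm.relax_to_consensus(dataset.configs, iterations=3)
print("bending energy per iteration:", [round(e, 1) for e in trace.energies])

means = cm.species_means(configs)
species = sorted(means)
aligned = cm.gpa(np.stack([means[s].mean_form for s in species]))
shapes = {s: aligned.shapes[i].ravel() for i, s in enumerate(species)}
log_cs = {s: float(np.log(means[s].mean_cs)) for s in species}

k = cm.blomberg_k(dataset.tree, log_cs, n_perm=10000, seed=1)
km = cm.k_mult(dataset.tree, shapes, n_perm=10000, seed=2)
print(f"K(size) = {k.statistic:.3f} (p = {k.p_value:.4f}); "
      f"Kmult(shape) = {km.statistic:.3f} (p = {km.p_value:.4f})")

X = np.vstack([shapes[s] for s in species])
groups = [dataset.traits[s] for s in species]
scores = cm.retain_pcs(X, 0.95).scores[:, :16]
rep = cm.bgpca_classify(scores, groups, cross_validate=True)
perm = cm.permutation_group_distance(scores, groups, n_perm=10000, seed=3)
print(f"bgPCA cross-validated accuracy = {rep.accuracy:.0f}%; "
      f"permutation p = {perm.p_value:.4f}")

rates = cm.rr_rates(dataset.tree, {s: scores[i] for i, s in enumerate(species)})
shifts = cm.search_shift_clades(dataset.tree, rates, n_rand=1000, seed=4)
print("significant rate-shift clades:", shifts.significant().index.tolist())
```

Output:

```
75 specimens, 25 species
bending energy per iteration: [11796.9, 4411.4, 3302.6, 2707.8]
K(size) = 0.398 (p = 0.5128); Kmult(shape) = 0.718 (p = 0.0001)
bgPCA cross-validated accuracy = 84%; permutation p = 0.0002
significant rate-shift clades: []
```

Reading this: sliding reduces total bending energy monotonically across the
three relax iterations. Sizes were drawn independently of the tree, so
K(size) is far below the Brownian expectation of 1 and not significant,
while the Brownian-evolved shapes carry significant phylogenetic signal.
The planted VCL/HL shape offset lets the cross-validated between-group PCA
classifier recover 84% of species and the permutation test on the group
mean distance is strongly significant. No clade rate multiplier was
planted, and accordingly no clade shows a significant rate shift.

The same workflow is available from the shell:

```sh
callimorph simulate --seed 42 --out data/
callimorph run --config config.yaml --seed 42 --out results/
```

`run` writes a deterministic report bundle (MANCOVA table, classification
JSON, per-clade rate-shift CSVs, phylomorphospace node positions, sliding
trace, config echo) — rerunning with the same config and seed reproduces it
byte for byte.

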