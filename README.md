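# brocamorph

Cross-species cortical surface morphometry of Broca's area homologs.

Comparative neuroanatomists who want to ask "how much did a
cytoarchitectonic region grow between species, and in which direction?"
face a chain of standard but fiddly steps: project histological label
volumes onto reconstructed cortical surfaces, register every individual
surface to a species template on the sphere, aggregate the registered
labels into a probabilistic atlas, carry that atlas through a
template-to-template warp into the other species' space, and only then
compare sizes and locations. `brocamorph` implements that chain as a
tested, reusable library — motivated by the comparison of Brodmann areas
44 and 45 (Broca's area) between humans and chimpanzees — together with a
synthetic two-species population generator that provides ground truth for
every stage, something no real cross-species dataset can offer.

## What it computes

**Regional size and its cross-species ratio.** On a labeled surface with
per-vertex cortical thickness *t*, regional gray-matter volume is the
prism approximation V = Σ_v A_v t_v over labeled vertices, with A_v the
barycentric vertex area. After mapping a region from species A to the
species B template, the expansion factor is

    E = V_B(reference) / V_B(projected homolog),

i.e. how many times larger the region is in species B than its projected
homolog, measured on the same surface with the same thickness field.

**Hemispheric asymmetry.** For paired left/right regional areas, the
lateralization index LI = (L − R)/(L + R) and the Wilcoxon signed-rank
test with T = min(W⁺, W⁻). For untied samples with n ≤ 25 the two-sided
p-value is exact, computed from the full null distribution of signed-rank
sums (equivalent to enumerating all 2ⁿ sign assignments).

**Surface registration.** Two stages on the unit sphere: a rigid
alignment from matched landmark (inferior-frontal-gyrus analog) and
sulcal/gyral centroids solved as a weighted orthogonal Procrustes
problem, then a multiresolution nonrigid refinement minimizing

    E(δ) = Σ_v A_v (d_src(v) − d_dst(φ(v)))² + λ Σ_{(u,v)∈edges} ‖δ_u − δ_v‖²

over tangential control-vertex displacements δ, where d are z-scored
sulcal-depth maps. Accepted steps never increase the objective and never
fold a spherical triangle.

**Containment overlap.** For a functional subdivision F and a reference
region B on one mesh, area(F ∩ B)/area(F), optionally swept over atlas
thresholds (it is non-increasing in the threshold).

## Worked example

Build a chimpanzee-analog template, generate nine synthetic subjects with
ring-level label jitter (the delineation-variability model), and test
BA44 surface-area symmetry:

```python
from brocamorph import PopulationSpec, expansion_factor, make_population, make_template
from brocamorph.atlas_stats import asymmetry_analysis
from brocamorph.synthetic import chimp_like

template = make_template(chimp_like(seed=0))
subjects, _ = make_population(
    template, PopulationSpec(n_subjects=9, warp_amplitude=0.0, label_jitter=1, seed=42)
)
report = asymmetry_analysis(subjects, label_id=1)
print(report.to_frame().round(1).to_string(index=False))
w = report.wilcoxon
print(f"Wilcoxon T = {w.T:g}, two-sided p = {w.p_two_sided:.3f} (n = {w.n_effective})")
print(f"left/right BA44 fold change: {expansion_factor(3839.0, 2331.0):.2f}")
```

prints

```
subject  left_area_mm2  right_area_mm2  lateralization_index
 subj00         1117.4          1003.1                   0.1
 subj01         1117.4          1117.4                   0.0
 subj02         1117.4          1003.1                   0.1
 subj03          853.1          1117.4                  -0.1
 subj04         1003.1           853.1                   0.1
 subj05         1003.1          1003.1                   0.0
 subj06         1003.1          1117.4                  -0.1
 subj07          853.1          1117.4                  -0.1
 subj08         1003.1           853.1                   0.1
Wilcoxon T = 13, two-sided p = 0.932 (n = 7)
left/right BA44 fold change: 1.65
```

The per-subject areas fluctuate by one boundary ring of jitter; under
this symmetric null the test correctly finds no asymmetry (two subjects
with identical areas are dropped, leaving n = 7 effective pairs). The
last line is the fold change computed from published mean volumes of
human BA44 and of the chimpanzee homolog projected to the human template:
the human left BA44 is about 1.65 times larger.

The full pipeline is also scriptable from the shell via the `brocamorph`
command (`simulate`, `project`, `register`, `xregister`, `atlas`,
`asymmetry`, `compare`, `overlap`, `report`); `configs/small.yaml` is a
ready-made small configuration.

## Scope

The package operates on surfaces and label volumes that are already in a
common space; MRI preprocessing, surface reconstruction (FreeSurfer), and
histological delineation are upstream of it. The synthetic generator
emulates the geometry and statistics those upstream steps deliver, not
the imaging itself. See `docs/methods.md` for the model, parameter, and
design details.
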