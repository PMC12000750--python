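"""Single-cell nascent-protein quantification on a synthetic z-stack.

Generates a confocal-like 3-channel stack (nuclei / actin / nascent
protein) with 60 cells of known phenotype, runs the nuclei-seeded
segmentation + actin-subtraction workflow, and compares the recovered
negative / restricted / secreting fractions with the ground truth.
"""

import osteochip as oc

params = oc.PhenotypeParams(
    n_cells=60, fractions=(0.2, 0.3, 0.5), noise_gaussian_sd=3.0,
    shape=(36, 448, 448),
)
stack, truth = oc.generate_cell_stack(params, seed=7)
records, summary = oc.quantify_stack(stack)

true_fracs = truth["class_label"].value_counts(normalize=True)
print(f"cells quantified: {summary['n_cells']} (truth: {len(truth)})")
print("phenotype fractions (recovered vs truth):")
for cls in ("negative", "restricted", "secreting"):
    print(f"  {cls:10s} {summary['class_fractions'][cls]:.3f}"
          f"  vs  {true_fracs.get(cls, 0.0):.3f}")
secreting = records[records["class_label"] == "secreting"]
print(f"mean pericellular (extracellular) volume of secreting cells: "
      f"{secreting['extracellular_nascent_volume_um3'].mean():.0f} μm³")
# The fractions say how many cells deposit protein beyond the actin-defined
# cell body; the pericellular volume is the matrix each secreting cell laid
# down around itself.
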