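"""Generate a small synthetic ptosis cohort and inspect its anatomy.

Each eye gets ground-truth clinical parameters (MRD1, MRD2, levator
function...), a periocular mesh, landmark annotations in 2D and 3D, and
a surgery label from the standard rule: no surgery when MRD1 is
adequate, levator resection when levator function exceeds 4 mm,
frontalis suspension otherwise.
"""

from ptosiskit import CohortConfig
from ptosiskit.synthcohort import generate_cohort

config = CohortConfig(n_eyes=9, noise_sd_mm=0.2, seed=7)
cohort = generate_cohort(config)

print(f"{'eye':8s} {'side':6s} {'MRD1':>6s} {'levator':>8s} {'fissure':>8s}  label")
for eye in cohort:
    p = eye.phenotype
    print(
        f"{eye.eye_id:8s} {p.side:6s} {p.mrd1_mm:6.2f} {p.levator_function_mm:8.2f} "
        f"{p.fissure_width_mm:8.2f}  {eye.label.value}"
    )
print(
    "\nMRD1 < 2.5 mm means ptosis; among ptotic eyes, levator function"
    "\n> 4 mm selects levator resection, otherwise frontalis suspension."
)
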