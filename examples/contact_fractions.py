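"""Measure per-residue gold-contact fractions on a synthetic trajectory.

Generates a 5000-frame trajectory of a three-residue peptide above a
three-layer Au(111)-like slab with planted contact probabilities, then runs
the contact analysis and compares the estimates with the planted truth.
"""

import numpy as np

from pepsurf import ContactSpec, compute_contact_fractions, gen_contact_trajectory

planted = (0.9, 0.5, 0.1)
spec = ContactSpec(
    contact_probabilities=planted,
    residue_names=("TYR", "MET", "THR"),
    n_frames=5000,
    correlation=0.5,  # frames are temporally correlated, like real MD
    seed=7,
)
trajectory, truth = gen_contact_trajectory(spec)
profile = compute_contact_fractions(trajectory)

print("residue  planted p  estimated f")
for label, p, f in zip(profile.labels, planted, profile.fractions):
    print(f"{label:8s}    {p:.2f}      {f:.4f}")
print()
print("The contact fraction f is the share of frames in which the residue's")
print("reference site sits within its cut-off of the topmost gold layer;")
print("estimates match the planted probabilities to sampling error "
      f"(max |f-p| = {np.abs(profile.fractions - np.array(planted)).max():.4f}).")
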