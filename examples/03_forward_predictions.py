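"""Forward-predict NOESY heights, scalar couplings and RDCs.

Runs the three forward models on an ensemble sampled from the final fitted
model: the full relaxation-matrix NOESY prediction at 900 MHz / 700 ms, the
Karplus-averaged <3J(HH)> couplings, and shape-alignment RDCs.
"""

import numpy as np

import ensemblefit as ef
from ensemblefit import fixtures as fx
from ensemblefit.jcoupling import ensemble_j_many
from ensemblefit.noe import SpinSystem, ensemble_r6, predict_noesy, relaxation_matrix
from ensemblefit.rdc import alignment_tensors, predict_rdc
from ensemblefit.restraints import JRestraint

template = fx.streptomycin_template()
model = fx.ground_truth_model()
ens = ef.sample_ensemble(model, template, n=1000, seed=2)

# NOESY: <r^-6> -> rate matrix -> exp(-R tau_mix)
spins = SpinSystem.from_template(template)
r6 = ensemble_r6(ens.coords, spins)
R = relaxation_matrix(r6, tau_c=1.5e-9, field_mhz=900.0,
                      multiplicity=spins.multiplicity)
H = predict_noesy(R, mixing_time=0.700)
i, j = spins.spin_of("R2_H1"), spins.spin_of("G3_H1")
print(f"predicted trans-glycosidic cross peak R2_H1/G3_H1: {abs(H[i, j]):.4f} "
      "(one-mole-equivalent units)")
i2, j2 = spins.spin_of("S1_H4"), spins.spin_of("R2_H1")
print(f"predicted S1_H4/R2_H1 cross peak: {abs(H[i2, j2]):.4f}")

# scalar couplings
ksets = fx.default_karplus_sets()
jr = [JRestraint(q, 0.0, 1.0, kid) for q, kid in fx.streptomycin_j_specs()[:4]]
jvals = ensemble_j_many(ens.coords, template, jr, ksets)
for r, v in zip(jr, jvals):
    print(f"<3J> {r.atoms[0]}-{r.atoms[3]}: {v:.2f} Hz")

# RDCs from the molecular-surface alignment tensor, 18 Hz medium magnitude
radii = np.array([ef.geometry.VDW_RADII.get(a.element, 1.7)
                  for a in template.atoms])
tensors = alignment_tensors(ens.coords, radii=radii)
ci = np.array([template.index("G3_C1")])
hi = np.array([template.index("G3_H1")])
d = predict_rdc(ens.coords, tensors, ci, hi, scale=18.0)
print(f"predicted RDC G3_C1-H1 at scale 18 Hz: {d[0]:.2f} Hz")
# Cross peaks fall off as <r^-6>, couplings follow the Karplus curve of the
# averaged dihedral distribution, and RDCs report bond orientations relative
# to the ensemble's shape-alignment frame.
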