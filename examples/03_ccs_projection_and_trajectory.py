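"""Collision cross sections: projection approximation, trajectory method,
and the Mason-Schamp mobility conversion.

PA is the fast geometric screen (union of hard disks, orientation
averaged); TM integrates classical scattering trajectories in the
Lennard-Jones + charge-induced-dipole potential of the ion in N2.
"""

import math

from glyccs import fixtures
from glyccs.ccs import N2, TMSettings, mason_schamp, pa_ccs, tm_ccs
from glyccs.molecule import vdw_radius

# 1. PA of a single carbon sphere has an analytic answer: pi (r_C + r_probe)^2
sphere = fixtures.make_fixture("sphere")
res = pa_ccs(sphere, N2, n_orientations=2000, seed=1)
analytic = math.pi * (vdw_radius("C") + N2.probe_radius) ** 2
print(f"PA sphere: {res.omega:.2f} A^2 (analytic {analytic:.2f} A^2)")

# 2. TM on a charged dumbbell: the induced-dipole attraction enlarges the
#    cross section relative to the same neutral geometry
dumbbell = fixtures.make_fixture("dumbbell")
dumbbell.set_partial_charges([0.5, 0.5])
small = TMSettings(cycles=3, velocity_points=8, mc_points=80, orientations=120, seed=2)
charged = tm_ccs(dumbbell, N2, small)
dumbbell.set_partial_charges([0.0, 0.0])
neutral = tm_ccs(dumbbell, N2, small)
print(f"TM dumbbell: charged {charged.omega:.1f} +/- {charged.stderr:.1f} A^2, "
      f"neutral {neutral.omega:.1f} +/- {neutral.stderr:.1f} A^2")

# 3. Mason-Schamp: reduced mobility K0 = 1.0 cm^2/Vs for a 500 Da ion in N2
omega = mason_schamp(1.0, ion_mass=500.0, gas=N2, temperature=298.0, z=1)
print(f"Mason-Schamp: K0 = 1.0 cm^2/Vs, m = 500 Da -> {omega:.1f} A^2")
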