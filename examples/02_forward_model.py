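"""Classical properties of the spherical-conductor dipole forward model.

A current dipole inside a homogeneous conducting sphere produces a magnetic
field with a closed form; two properties make MEG source analysis special:
a dipole at the sphere centre is invisible, and so is any radially oriented
dipole.  Only tangential source components reach the sensors.
"""

import numpy as np

from olfactomap import dipole_field

sensor = np.array([0.0, 0.05, 0.11])       # m, just outside a 0.09 m head sphere
normal = sensor / np.linalg.norm(sensor)   # radial magnetometer

tangential = dipole_field([0.0, 0.045, 0.055], [1e-8, 0.0, 0.0], sensor, normal)
central = dipole_field([0.0, 0.0, 0.0], [1e-8, 0.0, 0.0], sensor, normal)
radial_dir = np.array([0.0, 0.045, 0.055]) / np.linalg.norm([0.0, 0.045, 0.055])
radial = dipole_field([0.0, 0.045, 0.055], 1e-8 * radial_dir, sensor, normal)
doubled = dipole_field([0.0, 0.045, 0.055], [2e-8, 0.0, 0.0], sensor, normal)

print(f"tangential 10 nAm dipole:  {tangential * 1e15:10.3f} fT")
print(f"same dipole, doubled:      {doubled * 1e15:10.3f} fT   (exactly 2x: linearity)")
print(f"dipole at sphere centre:   {central * 1e15:10.3e} fT   (zero by symmetry)")
print(f"radially oriented dipole:  {radial * 1e15:10.3e} fT   (silent in a sphere)")
print(
    "\nTens to hundreds of fT against a few fT/sqrt(Hz) of sensor noise is "
    "the typical\nworking regime of whole-head MEG."
)
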