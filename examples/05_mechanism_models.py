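"""Mechanism models: electrostatics, gating, membrane, plasticity.

Solves the radial Poisson-Boltzmann problem around a charged 1 um
microsphere, evaluates Boltzmann channel gating, relaxes a two-channel
membrane to its steady state, and runs the CS-dependent Hebbian rule.
"""

import numpy as np
from scipy.constants import Boltzmann as K_B

import protospike as ps
from protospike import mechanism as mech

# electrostatics: screened surface potential
base = mech.ElectrolyteSystem(surface_charge=1e-3)
lam = mech.debye_length(base)
system = mech.ElectrolyteSystem(
    surface_charge=1e-3, outer_radius=base.inner_radius + 12 * lam
)
r, psi = mech.solve_pb_radial(system, 3000)
print(f"Debye length           : {lam * 1e9:.2f} nm")
print(f"surface potential      : {psi[0] * 1e3:.3f} mV")
print(f"potential at 3 Debye   : {np.interp(base.inner_radius + 3 * lam, r, psi) * 1e3:.4f} mV")

# gating: a channel destabilized by 2 kT is mostly closed
p = ps.channel_open_probability(2 * K_B * 298.15, 298.15)
print(f"open probability (2 kT): {p:.3f}")

# membrane: two conductances relax to the weighted reversal
model = mech.MembraneModel(
    channels=(mech.Channel(0.3, -80.0), mech.Channel(0.1, 20.0))
)
t, v = mech.simulate_membrane(model, v0=0.0, duration=200.0, dt=0.1)
print(f"membrane steady state  : {v[-1]:.2f} mV (expected {mech.membrane_steady_state(model):.2f})")

# plasticity: learning rate saturates with CS concentration
eta = mech.michaelis_learning_rate(0.1, 1.0)
for cs in (0.5, 1.86, 10.2):
    net = mech.PlasticNetwork(
        weights=np.zeros((1, 1)), cs=cs, x=[1.0], y=[1.0], learning_rate=eta
    )
    print(f"dw after 1 s at CS {cs:5.2f} mg/ml: {mech.hebbian_step(net, 1.0)[0, 0]:.4f}")
# The potential decays over a few nm (strong screening at 0.1 M), and the
# Hebbian increment grows but saturates with CS - bounded plasticity.
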