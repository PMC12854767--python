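"""Accuracy of hybrid short-range-exact / long-range-multipole electrostatics.

A random charge cloud interacts with distant environment charges.  Within a
cutoff R_exact of the cloud centroid all Coulomb pairs are summed exactly;
beyond it a single-center traceless multipole expansion of order p is used.
The scan tabulates the absolute energy and maximum-force-component errors
against the fully exact reference.
"""

import numpy as np

from mpakit import convergence_scan, make_charge_cloud

cloud, _ = make_charge_cloud(20, extent=4.0, net_charge=0.0, seed=1)
env, _ = make_charge_cloud(60, extent=60.0, seed=2)
far = np.linalg.norm(env.positions - cloud.centroid, axis=1) > 8.0
scan = convergence_scan(
    cloud,
    env.positions[far],
    env.charges[far],
    r_values=[0.0, 20.0, 1e4],
    p_values=[0, 2, 4, 8],
)
print(scan.to_string(index=False, float_format=lambda v: f"{v:.3e}"))
print("(abs_dE / abs_dFmax in a.u.; errors fall with multipole order and")
print(" vanish when R_exact covers every environment charge)")
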