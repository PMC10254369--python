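"""Reaction yields on a two-basin toy network, by contraction and by ODE.

The wall-channel fixture is a reactant basin A and a deeper product basin B
separated by a ~53 kJ/mol barrier.  Rate constants come from transition-state
theory on the refined barriers; populations after 1 s of reaction time are
computed twice — by rate-constant-matrix contraction and by direct stiff
integration — and should agree to well below a percentage point.
"""

import numpy as np

from forcepath.fixtures import FixtureSpec, make_fixture
from forcepath.kinetics import build_rate_model, ode_oracle, rcmc_contract, yield_report

fixture = make_fixture(FixtureSpec("wall_channel", rng_seed=0))
net = fixture.network
product_ids = [r.eq_id for r in net.eqs if fixture.is_product(r.geometry)]
print(f"network: {net.n_eqs} EQs, {len(net.paths)} refined paths; product EQ(s): {product_ids}")

p0 = np.zeros(net.n_eqs)
p0[0] = 1.0  # all population starts in the reactant basin
print(f"{'T (K)':>6} {'yield RCMC %':>13} {'yield ODE %':>12}")
for T in (250.0, 300.0, 350.0):
    model = build_rate_model(net, T)
    y_rcmc = yield_report(rcmc_contract(model, 1.0, p0), product_ids)
    y_ode = yield_report(ode_oracle(model, p0, 1.0), product_ids)
    print(f"{T:6.0f} {y_rcmc:13.3f} {y_ode:12.3f}")
print("\n(yields dip slightly with T: the 12 kJ/mol exothermicity pulls the")
print(" equilibrium a little toward the reactant at higher temperature)")
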