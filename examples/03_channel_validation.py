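"""Validate the flow solver against closed-form channel solutions.

Solves steady flow in a straight parent-vessel channel twice -- Newtonian
and Casson -- and compares the velocity profile and wall shear stress with
the analytic plane-Poiseuille and two-zone plane-Casson solutions.
"""

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from hemoflow import CassonParams, build_2d_domain, inlet_profile, steady_solve
from hemoflow.hemodynamics import wall_shear_stress

dom = build_2d_domain(None, mesh_size=0.2)  # 4 mm channel, 40 mm long

# --- Newtonian: parabolic profile ------------------------------------------
newt = CassonParams(tau_y=0.0, k=0.0035)
sol = steady_solve(dom, newt, q_ml_s=2.6)
y = dom.face_y()
ana = inlet_profile(2.6, y, dom.channel_height)
err = np.linalg.norm(sol.u[0][dom.nx // 2] - ana) / np.linalg.norm(ana)
print(f"Poiseuille: L2 velocity error vs analytic parabola = {100*err:.4f}%")

# --- Casson: two-zone profile with a plug core ------------------------------
params = CassonParams(tau_y=0.01, k=0.0035)
q_ml = 0.6
H, a = dom.channel_height, dom.channel_height / 2
u_mean = q_ml / (0.25 * np.pi * (H * 1e3) ** 2)


def gdot(tau):
    return (np.sqrt(tau) - np.sqrt(params.tau_y)) ** 2 / params.k if tau > params.tau_y else 0.0


def q_of_tw(tw):
    return 2 * quad(lambda yy: quad(lambda s: gdot(tw / a * s), yy, a)[0], 0, a)[0]


tw_ref = brentq(lambda t: q_of_tw(t) - u_mean * H, 1e-6, 100.0)
solc = steady_solve(dom, params, q_ml)
wf = wall_shear_stress(solc, params)
mid = (wf.positions[:, 1] < 1e-12) & (wf.positions[:, 0] > 0.6 * dom.length) & (wf.positions[:, 0] < 0.9 * dom.length)
wss = wf.wss[mid, 0].mean()
print(f"Casson: solver wall shear stress = {wss:.4f} Pa, analytic = {tw_ref:.4f} Pa "
      f"({100*abs(wss-tw_ref)/tw_ref:.2f}% off)")
print()
print("The plug core (stress below the yield stress) flattens the centreline")
print("profile and raises the wall stress relative to a Newtonian fluid of the")
print("same plateau viscosity at this low flow rate.")
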