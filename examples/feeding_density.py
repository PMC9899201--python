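"""Reconstructing the feeding-duration density n(t, a).

The feeding population is structured by time-since-attachment a on [0, T];
its density is the attachment inflow rho(F) Q discounted by grooming
survival.  The integral of n(t, .) over [0, T] recovers F(t) exactly, and
n(t, 0) is the instantaneous attachment flux.
"""

from scipy.integrate import simpson

from tickdae import density_profile, make_history, simulate
from tickdae.experiments import get_preset

preset = get_preset("quadri")
params, scenario = preset.params, preset.scenario
h = params.T / 70

history = make_history("matched", 300.0, params, scenario, h=h)
traj = simulate(history, params, scenario, t_end=2 * (params.tau + params.T),
                h=h, equilibria=[])

t = 1000.0
a, n = density_profile(traj, t)
i = round(t / traj.h)
print(f"t = {t:.0f} days: F(t) = {traj.F[i]:.6f}, "
      f"integral of n(t,.) over [0,T] = {simpson(n, x=a):.6f}")
print(f"attachment flux n(t,0) = {n[0]:.6f} = rho(F) * Q "
      f"(Q(t) = eta E(t - tau) = {traj.Q[i]:.6f})")
print("density at a = 0, T/2, T:", n[0], n[len(n) // 2], n[-1])

# The profile decays with a: ticks that attached longer ago have survived
# more grooming, so fewer of them remain attached.
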