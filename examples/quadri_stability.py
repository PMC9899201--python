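"""Quadri-stability: equilibrium structure of biting-reactive grooming.

Solves the attachment-level equation rho e^{-kT rho} = delta/eta for the
Holling-III + reactive-grooming preset, inverts the attachment curve, and
classifies every equilibrium by the sign of the feedback constant A.
"""

from tickdae import A_value, classify_reactive
from tickdae.experiments import get_preset

preset = get_preset("quadri")
params = preset.params

print(f"existence condition: delta/eta = {params.delta / params.eta:.4f} "
      f"< (e k T)^-1 = {1 / (2.718281828459045 * params.k * params.T):.4f}")
print(f"{'branch':12s} {'E*':>10s} {'F*':>10s} {'A':>9s}  verdict")
for eq in classify_reactive(params):
    A = A_value(eq, params).A if not eq.is_trivial else float("nan")
    print(f"{eq.branch:12s} {eq.E_star:10.4f} {eq.F_star:10.4f} {A:9.4f}  {eq.stability}")

# The two positive equilibria with A > 0 attract: one combines a high
# attachment level with few feeding ticks (plus_minus), the other a low
# attachment level with many feeding ticks (minus_plus).  Extinction is a
# third attractor, so the long-term tick burden depends on initial loads.
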