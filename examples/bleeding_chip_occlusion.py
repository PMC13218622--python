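"""Occlusion of the bleeding-chip injury channel under different rate families.

Runs the coarse 2D demo of the H-shaped extravascular-injury chip with the
tanh-on + exponential-off vWF rate family and prints the injury-channel flow
rate over time together with the occlusion time (flow below 35% of its initial
value).  Swap the preset name for "bleeding_chip_constant_demo" to see that
shear-independent rates fail to occlude the channel.
"""

from shearclot import get_preset, run_simulation

cfg = get_preset("bleeding_chip_tanh_exp_demo")
res = run_simulation(cfg)
s = res.series
print("   t (s)   injury flow (uL/min)")
for i in range(0, len(s.times), max(1, len(s.times) // 12)):
    print(f"{s.times[i]:8.2f} {s.injury_flow_rate[i]:16.4f}")
occ = res.occlusion["configured"]
occ = f"{occ:.2f} s" if isinstance(occ, float) else occ
print(f"\nocclusion time (35% of initial flow): {occ}")
print("The clot nucleates on the injury-channel walls, the lumen narrows,")
print("local shear rises into the 2000-8000/s range where the tanh on-rate")
print("and the slowly-growing exponential off-rate sustain cohesion, and the")
print("channel seals.")
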