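"""Evaluate uniporter Ca2+ uptake under both formulations.

Computes the net influx predicted by the generalized-GHK and
Eyring-barrier liver parameterizations over an external Ca2+ titration at
a fixed, energized membrane potential, and over a potential ramp at fixed
external Ca2+.
"""

import numpy as np

from mcuflux import flux, packaged_params

present = packaged_params("present/model1/liver")
previous = packaged_params("previous/model1/case1/liver")

ca_x = 250e-9          # matrix free Ca2+, molar
dpsi = 190.0           # membrane potential, mV

print("External Ca2+ titration at 190 mV (rates in nmol/mg/s):")
ca_e = np.geomspace(1e-6, 150e-6, 8)
j_ghk = flux(ca_e, np.full_like(ca_e, ca_x), np.full_like(ca_e, dpsi), present)
j_eyr = flux(ca_e, np.full_like(ca_e, ca_x), np.full_like(ca_e, dpsi), previous)
print(f"{'ca_e (µM)':>10} {'generalized':>12} {'barrier':>12}")
for c, a, b in zip(ca_e, j_ghk, j_eyr):
    print(f"{c * 1e6:10.2f} {a:12.4f} {b:12.4f}")

print("\nPotential ramp at 1 µM external Ca2+:")
dpsis = np.linspace(60.0, 190.0, 7)
j = flux(np.full_like(dpsis, 1e-6), np.full_like(dpsis, ca_x), dpsis, present)
for d, v in zip(dpsis, j):
    print(f"  {d:6.1f} mV  ->  {v:.5f} nmol/mg/s")
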