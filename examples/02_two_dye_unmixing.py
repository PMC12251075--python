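"""Recover two dye concentrations from dual-wavelength intensities.

Forward-models a Tartrazine/Erioglaucine mixture, then solves the 2x2
absorbance-space system A_w = sum_d eps_d(lambda_w) * L * C_d using readings
at 424 nm and 631 nm only.
"""

import numpy as np

import flowspec as fs

dyes = fs.default_dyes()  # (TZ, EG)
geometry = fs.FlowCellGeometry()
k = fs.build_cross_matrix(dyes, geometry)

print("cross-absorptivity matrix K (rows 424/631 nm, cols TZ/EG):")
print(np.array_str(k.matrix, precision=5))
print(f"condition number: {k.condition_number:.2f}")

truth = np.array([33.0, 4.17])  # ug/mL: the constant-flow steady state
intensities = np.power(10.0, -(k.matrix @ truth))
print(f"\ntrue mixture (TZ, EG) = {truth} ug/mL")
print(f"measured I/I0 at (424, 631) nm = {np.round(intensities, 4)}")

recovered = fs.recover_concentrations(intensities, k)
print(f"recovered (TZ, EG) = {np.round(recovered, 6)} ug/mL")
print("(exact to machine precision: with one wavelength per dye the "
      "log-linear Beer-Lambert system has a unique closed-form solution)")
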