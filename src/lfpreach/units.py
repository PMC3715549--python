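"""Unit conventions and conversion constants.

All geometry is in micrometres, currents in nA, extracellular conductivity in
S/m, extracellular potentials in microvolts, times in ms, frequencies in Hz.
Passive membrane parameters use the conventional electrophysiology units
(Ohm*cm for axial resistivity, Ohm*cm^2 for specific membrane resistance,
uF/cm^2 for specific membrane capacitance); the cable module converts them to
SI per-compartment quantities (farad, siemens) internally.
"""

# phi[uV] = POTENTIAL_PREFACTOR * I[nA] / (4*pi*sigma[S/m] * R[um])
# derivation: 1e-9 A / (S/m * 1e-6 m) = 1e-3 V = 1e3 uV
POTENTIAL_PREFACTOR = 1.0e3

UM_PER_CM = 1.0e4
CM2_PER_UM2 = 1.0e-8

# membrane capacitance: uF/cm^2 * um^2 -> F
CAPACITANCE_F_PER_UF_UM2 = 1.0e-6 * CM2_PER_UM2
# leak conductance: (1/(Ohm*cm^2)) * um^2 -> S
CONDUCTANCE_S_PER_INVOHMCM2_UM2 = CM2_PER_UM2
# axial conductance: cross-section um^2 / (Ohm*cm * um) -> S
# g = A/(Ra * L); A[um^2]=A*1e-8 cm^2, L[um]=L*1e-4 cm -> factor 1e-4
AXIAL_S_FACTOR = 1.0e-4

MS_PER_S = 1.0e3
S_PER_MS = 1.0e-3
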