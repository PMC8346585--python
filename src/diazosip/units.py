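"""Centralized unit-conversion constants.

Every cross-unit factor used anywhere in the package lives here, so the
fmol -> umol and m2/s -> m2/d chains can be audited in one place and are
never inlined at call sites.
"""

#: seconds in a day (turbulent diffusivity m2 s-1 -> m2 d-1)
SECONDS_PER_DAY = 86400.0

#: femtomoles per micromole (single-cell rates -> volumetric rates)
FMOL_PER_UMOL = 1e9

#: picomoles per mole
PMOL_PER_MOL = 1e12

#: millilitres per litre
ML_PER_L = 1e3

#: moles per mole -> parts per million
PPM = 1e6

#: 1 umol L-1 == 1 mmol m-3 (numerically identical; kept for audit clarity)
UMOL_L_PER_MMOL_M3 = 1.0

#: ideal-gas molar volume at 0 degC, 1 atm [L mol-1]
MOLAR_VOLUME_STP = 22.414

#: molar mass of carbon [g mol-1]
CARBON_MOLAR_MASS = 12.0

#: default bulk-biomass C:N ratio [mol C / mol N]
DEFAULT_CN_RATIO = 8.6

#: 15N natural abundance [atom %] — used by the synthetic generator and
#: examples only; real runs take the reference from an unincubated control
N15_NATURAL_ABUNDANCE = 0.3663

#: 13C natural abundance [atom %] — synthetic defaults only
C13_NATURAL_ABUNDANCE = 1.11
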