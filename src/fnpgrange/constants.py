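"""Physical constants in the package's internal unit system (mm, ns, MeV).

The precision is fixed here once so that kinematic round-trips are exact:
the same constants are used by the synthetic interaction sampler and by the
cone reconstruction.
"""

#: Neutron rest energy, MeV (CODATA, truncated to the precision used throughout).
M_N_C2 = 939.56542

#: Electron rest energy, MeV.
M_E_C2 = 0.51100

#: Speed of light, mm/ns.
C_MM_NS = 299.792458

#: FWHM -> sigma divisor for Gaussian resolutions (2*sqrt(2*ln 2), printed precision).
FWHM_OVER_SIGMA = 2.3548

#: Species tags used in every event/collision table.
FN = "FN"
PG = "PG"
SUM = "SUM"
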