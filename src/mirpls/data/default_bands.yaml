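# Synthetic mid-IR band model for a five-component fermentation matrix,
# 850-1200 cm-1 fingerprint region.
#
# Each band is a Gaussian: amplitude * exp(-(nu - center)^2 / (2 width^2)),
# amplitude in absorbance units per 1 % w/w, center and width (Gaussian
# sigma) in cm-1.  Band centers follow the well-known C-O stretching /
# O-H bending assignments for ethanol and the fingerprint bands of the
# four sugars; widths (FWHM ~14-26 cm-1, typical of liquid-phase
# fingerprint bands) and amplitudes (~0.1 AU peak at 10 % w/w, ATR scale)
# are synthetic, with deliberate sugar-ethanol overlap at 1000-1100 cm-1 —
# the interference that makes multivariate calibration necessary.  The
# second-derivative recoverability contract of the simulator (ethanol
# RMSECV <= 0.1 % w/w at default noise) constrains widths from above:
# much broader bands carry too little curvature to survive derivative
# pre-treatment at instrument noise.  This file is a documented fixture,
# not instrument data.
ethanol:
  - {center: 1087.0, width: 9.0, amplitude: 0.010}   # C-O stretch
  - {center: 1045.0, width: 8.0, amplitude: 0.012}   # C-O stretch (strongest)
  - {center: 880.0,  width: 6.0, amplitude: 0.004}   # O-H bend / CH3 rock
glucose:
  - {center: 1033.0, width: 10.0, amplitude: 0.011}
  - {center: 1080.0, width: 11.0, amplitude: 0.008}
  - {center: 991.0,  width: 7.5,  amplitude: 0.005}
fructose:
  - {center: 1063.0, width: 10.0, amplitude: 0.010}
  - {center: 980.0,  width: 8.0,  amplitude: 0.007}
  - {center: 1145.0, width: 9.0,  amplitude: 0.004}
sucrose:
  - {center: 995.0,  width: 9.0,  amplitude: 0.011}
  - {center: 1055.0, width: 10.0, amplitude: 0.008}
  - {center: 925.0,  width: 7.0,  amplitude: 0.004}
maltose:
  - {center: 1029.0, width: 9.0,  amplitude: 0.010}
  - {center: 1078.0, width: 10.0, amplitude: 0.007}
  - {center: 905.0,  width: 7.0,  amplitude: 0.004}
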