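# Literature muscle force vectors for right-molar clenching (N), twelve
# masticatory muscles, in the mandible frame: x lateral (+right),
# y anterior (+forward), z superior (+up), origin mid-mandible.
# ATTACHMENT COORDINATES ARE SYNTHETIC: plausible mandible attachment
# points authored for this package (no measured coordinates exist for the
# published force table). Reaction magnitudes solved with them are
# geometry-dependent and are not reference values.
name,side,Fx_N,Fy_N,Fz_N,ax_mm,ay_mm,az_mm
SMR,right,-28.38,57.44,121.19,48.0,-10.0,10.0
DMR,right,-32.08,-21.03,44.53,45.0,-18.0,18.0
MPR,right,71.36,54.77,116.14,40.0,-12.0,5.0
ATR,right,-17.19,5.07,113.96,45.0,5.0,35.0
MTR,right,-14.01,-31.55,52.81,46.0,-5.0,38.0
PTR,right,-9.28,-38.14,21.14,47.0,-15.0,36.0
ILPR,right,12.63,15.17,-3.49,46.0,-28.0,28.0
MPL,left,-50.97,39.12,82.96,-40.0,-12.0,5.0
ATL,left,13.65,4.03,90.54,-45.0,5.0,35.0
MTL,left,14.22,-32.03,53.61,-46.0,-5.0,38.0
PTL,left,6.13,-25.21,13.98,-47.0,-15.0,36.0
ILPL,left,-27.35,32.87,-7.56,-46.0,-28.0,28.0
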