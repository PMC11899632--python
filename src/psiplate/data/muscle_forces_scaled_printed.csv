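# Published scaled muscle force vectors (N) used to simulate right-molar
# clenching after scaling the literature forces by the measured bite force.
# Kept for cross-checking the scaling operation; no attachment coordinates.
name,side,Fx_N,Fy_N,Fz_N
SMR,right,-7.09,14.36,30.30
DMR,right,-8.02,-5.26,11.13
MPR,right,17.84,13.69,29.04
ATR,right,-4.30,1.27,28.49
MTR,right,-3.50,-7.89,13.20
PTR,right,-2.32,-9.53,5.29
ILPR,right,3.16,3.79,-0.87
MPL,left,-12.74,9.78,20.74
ATL,left,3.41,1.01,22.64
MTL,left,3.55,-8.01,13.40
PTL,left,1.53,-6.30,3.49
ILPL,left,-6.84,8.22,-1.89
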