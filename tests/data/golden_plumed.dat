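# PLUMED input generated by sfacv
# slow-feature CVs as affine sin/cos torsion combinations
t_chi1_TRP41: TORSION ATOMS=615,617,619,622
t_chi2_TYR77: TORSION ATOMS=1204,1206,1208,1211
SF1: CUSTOM ARG=t_chi1_TRP41,t_chi2_TYR77 VAR=x0,x1 FUNC=0.125+(0.7*sin(x0))+(-0.3*cos(x0))+(0.45*sin(x1)) PERIODIC=NO
metad: METAD ARG=SF1 SIGMA=0.32 HEIGHT=1.5 PACE=500 BIASFACTOR=20 TEMP=300 FILE=HILLS
PRINT ARG=SF1,metad.bias STRIDE=500 FILE=COLVAR
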