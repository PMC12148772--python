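# aluminum
# density 2.699 g/cm3
# columns: energy_keV mu_rho_total mu_rho_pe mu_rho_incoh mu_rho_coh muen_rho
    5.00 1.934000e+02 1.845995e+02 4.848446e-02 8.751980e+00 1.846000e+02
    5.50 1.475811e+02 1.408656e+02 5.328171e-02 6.662240e+00 1.410306e+02
    6.00 1.153000e+02 1.100534e+02 5.832977e-02 5.188276e+00 1.103000e+02
    6.50 9.155134e+01 8.738539e+01 6.294738e-02 4.103000e+00 8.785971e+01
    7.00 7.394805e+01 7.058312e+01 6.736015e-02 3.297568e+00 7.117516e+01
    8.00 5.033000e+01 4.803979e+01 7.526618e-02 2.214948e+00 4.870000e+01
    9.00 3.568079e+01 3.405717e+01 8.109641e-02 1.542520e+00 3.456074e+01
   10.00 2.623000e+01 2.503643e+01 8.624235e-02 1.107326e+00 2.543000e+01
   11.00 1.981518e+01 1.891351e+01 9.108484e-02 8.105843e-01 1.907737e+01
   12.00 1.533922e+01 1.464122e+01 9.578862e-02 6.022063e-01 1.467437e+01
   13.00 1.212031e+01 1.152488e+01 1.000573e-01 4.953725e-01 1.152729e+01
   14.00 9.745600e+00 9.215962e+00 1.045329e-01 4.251060e-01 9.218663e+00
   15.00 7.955000e+00 7.483999e+00 1.088169e-01 3.621842e-01 7.487000e+00
   16.00 6.591595e+00 6.137271e+00 1.127717e-01 3.415523e-01 6.140575e+00
   17.00 5.524493e+00 5.093589e+00 1.164371e-01 3.144664e-01 5.097200e+00
   18.00 4.677131e+00 4.272482e+00 1.198460e-01 2.848031e-01 4.276401e+00
   19.00 3.995558e+00 3.617775e+00 1.230263e-01 2.547562e-01 3.622005e+00
   20.00 3.441000e+00 3.089459e+00 1.259723e-01 2.255690e-01 3.094000e+00
   22.00 2.647436e+00 2.295816e+00 1.310059e-01 2.206142e-01 2.300971e+00
   24.00 2.083916e+00 1.750131e+00 1.354649e-01 1.983198e-01 1.755901e+00
   26.00 1.672091e+00 1.362895e+00 1.394425e-01 1.697528e-01 1.369280e+00
   28.00 1.363732e+00 1.080721e+00 1.417816e-01 1.412299e-01 1.087659e+00
   30.00 1.128000e+00 8.703322e-01 1.435049e-01 1.141630e-01 8.778000e-01
   33.00 8.989182e-01 6.451666e-01 1.457442e-01 1.080074e-01 6.534165e-01
   36.00 7.306603e-01 4.900375e-01 1.476370e-01 9.298577e-02 4.990542e-01
   40.00 5.685000e-01 3.500925e-01 1.496299e-01 6.877753e-02 3.601000e-01
   44.00 4.721765e-01 2.594285e-01 1.501115e-01 6.263654e-02 2.703157e-01
   48.00 3.985644e-01 1.963145e-01 1.503991e-01 5.185082e-02 2.080483e-01
   52.00 3.464744e-01 1.521426e-01 1.505310e-01 4.380073e-02 1.646911e-01
   56.00 3.090203e-01 1.202677e-01 1.501512e-01 3.860150e-02 1.335655e-01
   60.00 2.778000e-01 9.589411e-02 1.495889e-01 3.231702e-02 1.099000e-01
   65.00 2.541619e-01 7.584707e-02 1.488240e-01 2.949077e-02 9.069691e-02
   70.00 2.340734e-01 6.030112e-02 1.477327e-01 2.603958e-02 7.592264e-02
   75.00 2.168014e-01 4.799661e-02 1.465485e-01 2.225624e-02 6.433986e-02
   80.00 2.018000e-01 3.827206e-02 1.437562e-01 1.977174e-02 5.511000e-02
   90.00 1.845656e-01 2.779696e-02 1.365260e-01 2.024265e-02 4.525336e-02
  100.00 1.704000e-01 2.002567e-02 1.298108e-01 2.056353e-02 3.794000e-02
  110.00 1.621033e-01 1.707700e-02 1.241645e-01 2.086183e-02 3.540486e-02
  120.00 1.548823e-01 1.455499e-02 1.192108e-01 2.111655e-02 3.323866e-02
  130.00 1.485240e-01 1.237216e-02 1.148176e-01 2.133425e-02 3.136319e-02
  140.00 1.428700e-01 1.046391e-02 1.108858e-01 2.152032e-02 2.972125e-02
  150.00 1.378000e-01 8.781378e-03 1.073394e-01 2.167922e-02 2.827000e-02
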