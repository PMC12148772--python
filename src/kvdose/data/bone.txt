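# bone
# density 1.85 g/cm3
# columns: energy_keV mu_rho_total mu_rho_pe mu_rho_incoh mu_rho_coh muen_rho
    5.00 2.050000e+02 1.949995e+02 5.087337e-02 9.949614e+00 1.950000e+02
    5.50 1.562886e+02 1.486315e+02 5.573251e-02 7.601356e+00 1.486321e+02
    6.00 1.220000e+02 1.159993e+02 6.112826e-02 5.939571e+00 1.160000e+02
    6.50 9.689427e+01 9.212842e+01 6.606410e-02 4.699784e+00 9.229113e+01
    7.00 7.828082e+01 7.443050e+01 7.072277e-02 3.779603e+00 7.468344e+01
    8.00 5.330000e+01 5.067838e+01 7.924889e-02 2.542368e+00 5.100000e+01
    9.00 3.830880e+01 3.631257e+01 8.560004e-02 1.910631e+00 3.631402e+01
   10.00 2.851000e+01 2.679829e+01 9.110197e-02 1.620607e+00 2.680000e+01
   11.00 2.175957e+01 2.039429e+01 9.614669e-02 1.269131e+00 2.039627e+01
   12.00 1.700281e+01 1.589388e+01 1.011766e-01 1.007753e+00 1.589614e+01
   13.00 1.355100e+01 1.263618e+01 1.057416e-01 8.090791e-01 1.263873e+01
   14.00 1.098320e+01 1.021828e+01 1.103200e-01 6.546004e-01 1.022113e+01
   15.00 9.032000e+00 8.384831e+00 1.149020e-01 5.322669e-01 8.388000e+00
   16.00 7.524089e+00 6.935127e+00 1.191323e-01 4.698302e-01 6.938618e+00
   17.00 6.337747e+00 5.802273e+00 1.230532e-01 4.124201e-01 5.806089e+00
   18.00 5.391088e+00 4.904022e+00 1.267002e-01 3.603663e-01 4.908165e+00
   19.00 4.626128e+00 4.182504e+00 1.301029e-01 3.135209e-01 4.186978e+00
   20.00 4.001000e+00 3.596195e+00 1.332863e-01 2.715187e-01 3.601000e+00
   22.00 3.088946e+00 2.701835e+00 1.387226e-01 2.483885e-01 2.707293e+00
   24.00 2.439131e+00 2.080465e+00 1.434952e-01 2.151709e-01 2.086577e+00
   26.00 1.962797e+00 1.635305e+00 1.477533e-01 1.797382e-01 1.642071e+00
   28.00 1.605135e+00 1.308042e+00 1.507027e-01 1.463908e-01 1.315417e+00
   30.00 1.331000e+00 1.062062e+00 1.525490e-01 1.163895e-01 1.070000e+00
   33.00 1.057903e+00 7.947189e-01 1.549491e-01 1.082345e-01 8.034899e-01
   36.00 8.578219e-01 6.090116e-01 1.569787e-01 9.183152e-02 6.185988e-01
   40.00 6.655000e-01 4.400513e-01 1.592170e-01 6.623165e-02 4.507000e-01
   44.00 5.490502e-01 3.287956e-01 1.598953e-01 6.035935e-02 3.403924e-01
   48.00 4.606273e-01 2.509439e-01 1.602085e-01 4.947499e-02 2.634431e-01
   52.00 3.978369e-01 1.958715e-01 1.603551e-01 4.161040e-02 2.092389e-01
   56.00 3.524137e-01 1.557502e-01 1.600932e-01 3.657034e-02 1.699285e-01
   60.00 3.148000e-01 1.250665e-01 1.594962e-01 3.023733e-02 1.400000e-01
   65.00 2.859702e-01 9.913061e-02 1.586835e-01 2.815605e-02 1.149642e-01
   70.00 2.616372e-01 7.912767e-02 1.576206e-01 2.488901e-02 9.579474e-02
   75.00 2.408486e-01 6.339575e-02 1.563582e-01 2.109467e-02 8.083299e-02
   80.00 2.229000e-01 5.128986e-02 1.508612e-01 2.074894e-02 6.896000e-02
   90.00 2.023050e-01 3.721142e-02 1.437760e-01 2.131760e-02 5.559481e-02
  100.00 1.855000e-01 2.696328e-02 1.368570e-01 2.167972e-02 4.585000e-02
  110.00 1.759091e-01 2.272123e-02 1.311520e-01 2.203586e-02 4.208052e-02
  120.00 1.675870e-01 1.914664e-02 1.261029e-01 2.233740e-02 3.891051e-02
  130.00 1.602795e-01 1.609412e-02 1.215923e-01 2.259306e-02 3.620571e-02
  140.00 1.537982e-01 1.345810e-02 1.175302e-01 2.280984e-02 3.386936e-02
  150.00 1.480000e-01 1.115993e-02 1.138466e-01 2.299347e-02 3.183000e-02
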