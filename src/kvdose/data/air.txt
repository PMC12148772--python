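# air
# density 0.00120479 g/cm3
# columns: energy_keV mu_rho_total mu_rho_pe mu_rho_incoh mu_rho_coh muen_rho
    5.00 4.027000e+01 3.949937e+01 6.579853e-02 7.048317e-01 3.950000e+01
    5.50 3.032704e+01 2.974668e+01 7.177129e-02 5.085847e-01 2.977263e+01
    6.00 2.341000e+01 2.296201e+01 7.723187e-02 3.707556e-01 2.300000e+01
    6.50 1.843585e+01 1.795656e+01 8.157374e-02 3.977255e-01 1.795757e+01
    7.00 1.477804e+01 1.427913e+01 8.543311e-02 4.134795e-01 1.428026e+01
    8.00 9.921000e+00 9.448603e+00 9.231711e-02 3.800801e-01 9.450000e+00
    9.00 6.997067e+00 6.565228e+00 9.901459e-02 3.328248e-01 6.566907e+00
   10.00 5.120000e+00 4.740030e+00 1.050134e-01 2.749570e-01 4.742000e+00
   11.00 3.903164e+00 3.517263e+00 1.112350e-01 2.746667e-01 3.519549e+00
   12.00 3.046670e+00 2.678321e+00 1.169825e-01 2.513661e-01 2.680934e+00
   13.00 2.425777e+00 2.084196e+00 1.221983e-01 2.193821e-01 2.087141e+00
   14.00 1.964331e+00 1.652029e+00 1.269610e-01 1.853410e-01 1.655311e+00
   15.00 1.614000e+00 1.330378e+00 1.313329e-01 1.522893e-01 1.334000e+00
   16.00 1.370227e+00 1.084581e+00 1.351541e-01 1.504910e-01 1.088542e+00
   17.00 1.174881e+00 8.949705e-01 1.386326e-01 1.412774e-01 8.992693e-01
   18.00 1.016282e+00 7.464257e-01 1.418624e-01 1.279939e-01 7.510649e-01
   19.00 8.860144e-01 6.284436e-01 1.448705e-01 1.127003e-01 6.334247e-01
   20.00 7.779000e-01 5.335761e-01 1.476797e-01 9.664425e-02 5.389000e-01
   22.00 6.463875e-01 3.953329e-01 1.509062e-01 1.001484e-01 4.012706e-01
   24.00 5.458400e-01 3.000271e-01 1.534196e-01 9.239326e-02 3.065617e-01
   26.00 4.672168e-01 2.321850e-01 1.556224e-01 7.940947e-02 2.393108e-01
   28.00 4.045572e-01 1.825642e-01 1.575624e-01 6.443056e-02 1.902749e-01
   30.00 3.538000e-01 1.454114e-01 1.592778e-01 4.911088e-02 1.537000e-01
   33.00 3.147208e-01 1.084192e-01 1.604045e-01 4.589710e-02 1.174990e-01
   36.00 2.828258e-01 8.211017e-02 1.611111e-01 3.960450e-02 9.194975e-02
   40.00 2.485000e-01 5.751003e-02 1.617782e-01 2.921178e-02 6.833000e-02
   44.00 2.303167e-01 4.320497e-02 1.615994e-01 2.551231e-02 5.492535e-02
   48.00 2.148809e-01 3.242206e-02 1.611907e-01 2.126820e-02 4.499787e-02
   52.00 2.034088e-01 2.504861e-02 1.605568e-01 1.780338e-02 3.843281e-02
   56.00 1.950084e-01 2.007377e-02 1.577450e-01 1.718963e-02 3.404411e-02
   60.00 1.875000e-01 1.599595e-02 1.539482e-01 1.755585e-02 3.041000e-02
   65.00 1.813135e-01 1.355126e-02 1.497624e-01 1.799984e-02 2.849473e-02
   70.00 1.757678e-01 1.139512e-02 1.459599e-01 1.841283e-02 2.682918e-02
   75.00 1.707575e-01 9.476301e-03 1.424834e-01 1.879774e-02 2.536621e-02
   80.00 1.662000e-01 7.755484e-03 1.392874e-01 1.915712e-02 2.407000e-02
   90.00 1.596993e-01 6.584046e-03 1.333444e-01 1.977090e-02 2.363363e-02
  100.00 1.541000e-01 5.553416e-03 1.282330e-01 2.031358e-02 2.325000e-02
  110.00 1.495363e-01 5.388949e-03 1.233772e-01 2.077007e-02 2.364112e-02
  120.00 1.454880e-01 5.243059e-03 1.190544e-01 2.119054e-02 2.400392e-02
  130.00 1.418608e-01 5.112344e-03 1.151679e-01 2.158061e-02 2.434259e-02
  140.00 1.385832e-01 4.994227e-03 1.116444e-01 2.194463e-02 2.466040e-02
  150.00 1.356000e-01 4.886718e-03 1.084272e-01 2.228608e-02 2.496000e-02
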