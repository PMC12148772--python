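# beryllium
# density 1.848 g/cm3
# columns: energy_keV mu_rho_total mu_rho_pe mu_rho_incoh mu_rho_coh muen_rho
    5.00 4.200000e+00 3.799273e+00 7.590873e-02 3.248184e-01 3.800000e+00
    5.50 3.182190e+00 2.800016e+00 8.037916e-02 3.017944e-01 2.800861e+00
    6.00 2.470000e+00 2.119032e+00 8.456345e-02 2.664045e-01 2.120000e+00
    6.50 1.996750e+00 1.642896e+00 8.875917e-02 2.650949e-01 1.643995e+00
    7.00 1.639833e+00 1.297900e+00 9.261706e-02 2.493159e-01 1.299131e+00
    8.00 1.150000e+00 8.484815e-01 1.003281e-01 2.011904e-01 8.500000e-01
    9.00 8.486062e-01 5.923305e-01 1.074430e-01 1.488328e-01 5.941524e-01
   10.00 6.466000e-01 4.291662e-01 1.137196e-01 1.037142e-01 4.313000e-01
   11.00 5.427417e-01 3.228966e-01 1.193170e-01 1.005281e-01 3.253492e-01
   12.00 4.625640e-01 2.487545e-01 1.240271e-01 8.978230e-02 2.515244e-01
   13.00 3.993101e-01 1.954095e-01 1.282894e-01 7.561122e-02 1.985007e-01
   14.00 3.484848e-01 1.560130e-01 1.321741e-01 6.029771e-02 1.594290e-01
   15.00 3.070000e-01 1.262689e-01 1.352840e-01 4.544711e-02 1.300000e-01
   16.00 2.863556e-01 1.044497e-01 1.372027e-01 4.470329e-02 1.084698e-01
   17.00 2.682295e-01 8.719561e-02 1.389639e-01 4.206995e-02 9.150463e-02
   18.00 2.521918e-01 7.334974e-02 1.405859e-01 3.825617e-02 7.794720e-02
   19.00 2.379050e-01 6.209155e-02 1.420840e-01 3.372947e-02 6.697680e-02
   20.00 2.251000e-01 5.282782e-02 1.434710e-01 2.880114e-02 5.800000e-02
   22.00 2.133513e-01 4.018943e-02 1.459550e-01 2.720686e-02 4.593227e-02
   24.00 2.031619e-01 3.085868e-02 1.470477e-01 2.525556e-02 3.712181e-02
   26.00 1.942188e-01 2.374290e-02 1.479506e-01 2.252535e-02 3.051741e-02
   28.00 1.862902e-01 1.817776e-02 1.487067e-01 1.940569e-02 2.545508e-02
   30.00 1.792000e-01 1.373618e-02 1.491924e-01 1.627137e-02 2.150000e-02
   33.00 1.740142e-01 1.047861e-02 1.492982e-01 1.423744e-02 1.892974e-02
   36.00 1.694111e-01 7.735669e-03 1.492777e-01 1.239774e-02 1.685254e-02
   40.00 1.640000e-01 4.850367e-03 1.463728e-01 1.277683e-02 1.464000e-02
   44.00 1.602700e-01 3.414837e-03 1.435173e-01 1.333785e-02 1.382377e-02
   48.00 1.569389e-01 2.122197e-03 1.409441e-01 1.387262e-02 1.311841e-02
   52.00 1.540671e-01 1.282528e-03 1.384207e-01 1.436383e-02 1.282145e-02
   56.00 1.515796e-01 8.225553e-04 1.359432e-01 1.481386e-02 1.286207e-02
   60.00 1.493000e-01 3.843916e-04 1.336720e-01 1.524361e-02 1.290000e-02
   65.00 1.466812e-01 8.637032e-05 1.308661e-01 1.572871e-02 1.314435e-02
   70.00 1.442976e-01 1.000000e-08 1.283044e-01 1.599315e-02 1.337470e-02
   75.00 1.421133e-01 9.848627e-09 1.259501e-01 1.616318e-02 1.359278e-02
   80.00 1.401000e-01 9.709101e-09 1.237740e-01 1.632599e-02 1.380000e-02
   90.00 1.361982e-01 9.438699e-09 1.197447e-01 1.645347e-02 1.400971e-02
  100.00 1.328000e-01 9.203203e-09 1.162280e-01 1.657199e-02 1.420000e-02
  110.00 1.294187e-01 8.968874e-09 1.127560e-01 1.666266e-02 1.436153e-02
  120.00 1.264070e-01 8.760163e-09 1.096585e-01 1.674852e-02 1.451060e-02
  130.00 1.236985e-01 8.572458e-09 1.068684e-01 1.683007e-02 1.464909e-02
  140.00 1.212426e-01 8.402259e-09 1.043348e-01 1.690777e-02 1.477850e-02
  150.00 1.190000e-01 8.246846e-09 1.020180e-01 1.698199e-02 1.490000e-02
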