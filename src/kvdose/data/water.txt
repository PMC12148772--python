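# water
# density 1 g/cm3
# columns: energy_keV mu_rho_total mu_rho_pe mu_rho_incoh mu_rho_coh muen_rho
    5.00 4.190000e+01 4.119929e+01 7.416644e-02 6.265440e-01 4.120000e+01
    5.50 3.151558e+01 3.085641e+01 8.085510e-02 5.783160e-01 3.085726e+01
    6.00 2.430000e+01 2.369901e+01 8.692519e-02 5.140698e-01 2.370000e+01
    6.50 1.915318e+01 1.866626e+01 9.158969e-02 3.953385e-01 1.866739e+01
    7.00 1.536525e+01 1.496470e+01 9.587958e-02 3.046723e-01 1.496597e+01
    8.00 1.033000e+01 1.004843e+01 1.035312e-01 1.780358e-01 1.005000e+01
    9.00 7.284029e+00 6.909207e+00 1.110872e-01 2.637349e-01 6.911090e+00
   10.00 5.329000e+00 4.941791e+00 1.177541e-01 2.694554e-01 4.944000e+00
   11.00 4.058573e+00 3.656425e+00 1.248442e-01 2.773039e-01 3.658992e+00
   12.00 3.165186e+00 2.776950e+00 1.312310e-01 2.570055e-01 2.779880e+00
   13.00 2.518098e+00 2.155676e+00 1.370268e-01 2.253949e-01 2.158978e+00
   14.00 2.037561e+00 1.704802e+00 1.423187e-01 1.904406e-01 1.708480e+00
   15.00 1.673000e+00 1.369941e+00 1.471760e-01 1.558830e-01 1.374000e+00
   16.00 1.421603e+00 1.114583e+00 1.513527e-01 1.556673e-01 1.119018e+00
   17.00 1.219971e+00 9.179574e-01 1.552170e-01 1.467962e-01 9.227704e-01
   18.00 1.056133e+00 7.641823e-01 1.588048e-01 1.331456e-01 7.693755e-01
   19.00 9.214563e-01 6.422431e-01 1.621460e-01 1.170672e-01 6.478181e-01
   20.00 8.096000e-01 5.443421e-01 1.652661e-01 9.999179e-02 5.503000e-01
   22.00 6.758746e-01 4.023601e-01 1.684701e-01 1.050444e-01 4.089888e-01
   24.00 5.731768e-01 3.046275e-01 1.712605e-01 9.728880e-02 3.119219e-01
   26.00 4.925424e-01 2.351569e-01 1.737055e-01 8.368001e-02 2.431107e-01
   28.00 4.280364e-01 1.844075e-01 1.758585e-01 6.777048e-02 1.930135e-01
   30.00 3.756000e-01 1.464495e-01 1.777616e-01 5.138893e-02 1.557000e-01
   33.00 3.359854e-01 1.090502e-01 1.787887e-01 4.814656e-02 1.191707e-01
   36.00 3.034800e-01 8.239309e-02 1.795704e-01 4.151646e-02 9.336004e-02
   40.00 2.683000e-01 5.741080e-02 1.803070e-01 3.058224e-02 6.947000e-02
   44.00 2.497652e-01 4.311094e-02 1.799833e-01 2.667094e-02 5.616465e-02
   48.00 2.339645e-01 3.224979e-02 1.795254e-01 2.218939e-02 4.625604e-02
   52.00 2.222088e-01 2.485776e-02 1.787305e-01 1.862048e-02 3.975696e-02
   56.00 2.136078e-01 2.001196e-02 1.745725e-01 1.902333e-02 3.547259e-02
   60.00 2.059000e-01 1.593434e-02 1.705200e-01 1.944566e-02 3.190000e-02
   65.00 1.994668e-01 1.356675e-02 1.659542e-01 1.994592e-02 3.012585e-02
   70.00 1.936900e-01 1.146059e-02 1.618163e-01 2.041311e-02 2.857133e-02
   75.00 1.884623e-01 9.571416e-03 1.580407e-01 2.085020e-02 2.719629e-02
   80.00 1.837000e-01 7.864824e-03 1.545754e-01 2.125978e-02 2.597000e-02
   90.00 1.767193e-01 6.776143e-03 1.479994e-01 2.194380e-02 2.569954e-02
  100.00 1.707000e-01 5.817265e-03 1.423352e-01 2.254753e-02 2.546000e-02
  110.00 1.657205e-01 5.647569e-03 1.369688e-01 2.310417e-02 2.595646e-02
  120.00 1.613015e-01 5.496975e-03 1.321857e-01 2.361882e-02 2.641813e-02
  130.00 1.573406e-01 5.361991e-03 1.278807e-01 2.409790e-02 2.685008e-02
  140.00 1.537601e-01 5.239972e-03 1.239737e-01 2.454640e-02 2.725630e-02
  150.00 1.505000e-01 5.128872e-03 1.204028e-01 2.496833e-02 2.764000e-02
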