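route,response,tissue,beta0,coef1_name,coef1,coef2_name,coef2,bic,adj_r2,p_value
iv,k_max,lung,3.77,x1,0.01,x2,-0.11,5.54,0.93,0.03
iv,k_max,gi,48.2,x1,-0.08,x2,-1.47,15.8,0.99,0.02
iv,k_max,liver,317,hd,4.69,sa,-10.7,41.8,0.91,0.04
iv,k_max,spleen,-12300,x1,178,x2,5280,50.9,0.80,0.09
iv,k_max,kidney,2.02,x1,-0.49,x2,3.59,11.0,0.93,0.03
iv,k_max,rest,0.067,x1,0.12,x2,-0.38,5.21,0.83,0.08
iv,a_cap,lung,-448,x1,3.01,x2,44.7,35.8,0.97,0.01
iv,a_cap,gi,29.4,x1,-3.04,x2,46.6,34.7,0.98,0.01
iv,a_cap,liver,8210,x1,1080,x2,-251,69.7,0.95,0.03
iv,a_cap,spleen,-76.1,x1,131,x2,-151,74.7,0.91,0.05
iv,a_cap,kidney,228,x1,-64,x2,467,57.2,0.96,0.02
iv,a_cap,rest,-126,x1,12.2,x2,6.01,36.7,0.98,0.01
iv,k_release,lung,-4.17,x1,0.058,x2,1.78,-24.3,0.48,0.26
iv,k_release,gi,-1.17,x1,0.015,x2,-0.052,-23.5,0.99,0.001
iv,k_release,liver,0.07,x1,-0.0003,x2,-0.029,-15.4,0.07,0.49
iv,k_release,spleen,-0.22,x1,0.004,x2,-0.009,-56.5,0.99,3.64e-05
iv,k_release,kidney,4.56,x1,-0.03,x2,1.56,26.8,0.14,0.43
iv,k_release,rest,-0.11,x1,0.003,x2,0.031,-11.8,0.96,0.018
iv,k_excretion,urine,0.00035,x1,-0.0001,x2,0.00074,-76.4,0.96,0.019
iv,k_excretion,feces,-1.36,x1,0.002,x2,0.054,-18.1,0.97,0.015
iv,k_excretion,biliary,0.03,x1,0.00014,x2,0.001,-58.6,0.98,0.001
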