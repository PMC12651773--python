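plant_source,solubility,alpha_helix,random_coil,digestibility,prediction,percentage_error
Lentil protein,92.7,10.44,17.43,84.9,93.5,10.13
Quinoa protein,82.94,19.99,16.91,81.07,83.58,3.1
Quinoa protein,87.0,17.49,18.24,84.06,82.39,1.99
Quinoa protein,88.53,16.74,18.44,85.15,92.07,8.13
Pearl millet protein,60.0,30.19,25.79,71.73,65.92,8.1
Pearl millet protein,62.35,21.48,32.8,75.89,69.16,8.87
Kiwifruit protein,16.51,15.0,33.0,35.0,35.28,0.8
Kiwifruit protein,14.54,10.0,32.0,44.0,43.56,1.0
Sunflower meal protein,64.48,15.54,17.69,93.67,83.97,10.36
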