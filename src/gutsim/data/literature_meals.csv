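meal_label,half_time_min,kcal,viscosity_class,method
500mL 0.25% LBG,17,,LV,mri
500mL 0.5% LBG,18,,LV,mri
500mL 1.0% LBG,18,,HV,mri
500mL 1.5% LBG,19,,HV,mri
500mL 64kcal LV,32,64,LV,mri
500mL 64kcal HV,46,64,HV,mri
500mL 322.65kcal LV,67,322.65,LV,mri
500mL 322.65kcal HV,79,322.65,HV,mri
600mL 96kcal glucose LV,17,96,LV,aspiration
600mL 96kcal glucose HV,14,96,HV,aspiration
600mL 451kcal glucose LV,130,451,LV,aspiration
600mL 451kcal glucose HV,64,451,HV,aspiration
600mL 60kcal glucose,9.4,60,LV,aspiration
600mL 132kcal PPH,16.3,132,LV,aspiration
600mL 138kcal WPH,17.2,138,LV,aspiration
600mL 396kcal MP,26.4,396,LV,aspiration
300mL 400kcal glucose,107,400,LV,scintigraphy
450mL 200kcal glucose,66,200,LV,scintigraphy
500mL 500kcal mixed LV,72.1,500,LV,ultrasonography
500mL 500kcal mixed HV,85.5,500,HV,ultrasonography
400mL 400kcal mixed LV,257.9,400,LV,breath_13C
400mL 400kcal mixed HV,195.1,400,HV,breath_13C
400mL water,99.4,0,LV,breath_13C
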