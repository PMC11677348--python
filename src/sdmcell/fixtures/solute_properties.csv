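# Physicochemical and transport properties of the 14 feed solutes:
# NaCl background electrolyte plus 13 pharmaceutically active compounds.
# Molecular weight, log Kow and pKa are published measurement values;
# diffusion_coefficient_m2_s is NOT published for the pharmaceuticals and
# carries the package's molecular-weight correlation D = 1.2e-8 * MW^-0.53
# (m2/s); NaCl uses the standard aqueous value 1.61e-9 m2/s.
name,molecular_weight_g_mol,log_kow,pka,diffusion_coefficient_m2_s,osmotically_active,vant_hoff_factor
NaCl,58.44,,,1.610e-09,true,2
Acetaminophen,151.16,0.46,9.5,8.396e-10,false,1
Caffeine,194.19,-0.07,14.0,7.352e-10,false,1
Carbamazepine,236.27,2.45,13.9,6.626e-10,false,1
Diclofenac,296.15,4.51,4.0,5.879e-10,false,1
Ibuprofen,206.28,3.97,4.9,7.121e-10,false,1
Iopromide,791.12,2.60,3.4,3.492e-10,false,1
Lincomycin,406.53,-0.69,7.6,4.970e-10,false,1
Naproxen,230.26,3.18,4.15,6.717e-10,false,1
Propranolol,259.34,3.48,9.5,6.307e-10,false,1
Ranitidine,314.41,0.24,8.2,5.695e-10,false,1
Sulfamethoxazole,253.28,0.89,5.6,6.387e-10,false,1
Sulfamethazine,278.33,0.14,7.4,6.075e-10,false,1
Trimethoprim,290.32,0.91,7.2,5.941e-10,false,1
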