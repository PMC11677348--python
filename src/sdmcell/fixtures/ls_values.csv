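# Solute permeability coefficients Ls derived from the stirred-cell
# experiments, per membrane and compound. Transcribed values, printed as
# x1e-6 in the source experimental report; interpreted here as m/s and
# never rescaled. "Salt" is recorded under its identity, NaCl.
membrane,solute,Ls_m_s
NF,NaCl,3.492e-06
NF,Acetaminophen,1.745e-06
NF,Caffeine,0.838e-06
NF,Carbamazepine,1.281e-06
NF,Diclofenac,0.718e-06
NF,Ibuprofen,0.653e-06
NF,Iopromide,0.365e-06
NF,Lincomycin,0.335e-06
NF,Naproxen,0.725e-06
NF,Propranolol,1.212e-06
NF,Ranitidine,1.490e-06
NF,Sulfamethoxazole,0.575e-06
NF,Sulfamethazine,0.797e-06
NF,Trimethoprim,1.501e-06
RO,NaCl,0.170e-06
RO,Acetaminophen,0.178e-06
RO,Caffeine,0.044e-06
RO,Carbamazepine,0.073e-06
RO,Diclofenac,0.011e-06
RO,Ibuprofen,0.031e-06
RO,Iopromide,0.008e-06
RO,Lincomycin,0.015e-06
RO,Naproxen,0.027e-06
RO,Propranolol,0.035e-06
RO,Ranitidine,0.046e-06
RO,Sulfamethoxazole,0.025e-06
RO,Sulfamethazine,0.029e-06
RO,Trimethoprim,0.019e-06
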