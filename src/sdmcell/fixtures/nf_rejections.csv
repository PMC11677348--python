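# Run-averaged observed rejection (%) of 13 pharmaceuticals on the NF
# membrane (polyamide thin-film composite) in the dead-end stirred cell:
# 10 bar, 25 C, 500 mg/L NaCl background, 50 ng/L each compound,
# at two stirring speeds. Transcribed measurement values.
name,rejection_pct_300rpm,rejection_pct_450rpm
Acetaminophen,77.87,76.55
Caffeine,85.07,84.59
Carbamazepine,82.10,77.73
Diclofenac,86.06,89.58
Ibuprofen,87.88,89.20
Iopromide,92.80,93.23
Lincomycin,84.52,85.37
Naproxen,86.02,88.61
Propranolol,78.96,78.90
Ranitidine,77.03,75.60
Sulfamethoxazole,91.42,88.74
Sulfamethazine,85.76,87.73
Trimethoprim,77.12,79.87
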