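# Run-averaged observed rejection (%) of 13 pharmaceuticals on the RO
# membrane (dense seawater polyamide thin-film composite) in the dead-end
# stirred cell: 10 bar, 25 C, 500 mg/L NaCl background, 50 ng/L each
# compound, at two stirring speeds. Transcribed measurement values.
name,rejection_pct_300rpm,rejection_pct_450rpm
Acetaminophen,96.36,96.42
Caffeine,99.23,99.28
Carbamazepine,98.66,98.75
Diclofenac,99.82,99.87
Ibuprofen,99.37,99.46
Iopromide,99.85,99.85
Lincomycin,99.72,99.73
Naproxen,99.50,99.45
Propranolol,99.37,99.25
Ranitidine,99.19,99.30
Sulfamethoxazole,99.50,99.54
Sulfamethazine,99.43,99.38
Trimethoprim,99.68,99.60
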