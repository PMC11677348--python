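# Held-out validation conditions and the rejection rates reported for them
# (four compounds, one membrane/condition each). Qualitative reference only:
# the reported predictions cannot be recomputed without the unpublished
# water permeability, diffusion coefficients and stirring radius.
membrane,solute,pressure_bar,rpm,rejection_pct
NF,Acetaminophen,8,250,76.42
NF,Iopromide,6,500,95.69
RO,Sulfamethazine,9,200,99.18
RO,Caffeine,12,500,99.21
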