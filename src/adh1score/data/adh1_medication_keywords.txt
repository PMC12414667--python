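calcichew
calcichew d3 tablet
colecalciferol
cholecalciferol
calcitriol
calcium citrate
calcium carbonate
alfacalcidol
PTH
natpar
teriparatide
forteo
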