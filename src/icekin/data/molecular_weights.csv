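# molecular weights of colligative solutes, g/mol, v1
# maltodextrin/inulin are mean molecular weights (DE ~18 / DP ~10); override as needed
species,mw
sucrose,342.30
dextrose,180.16
fructose,180.16
sorbitol,182.17
lactose,342.30
maltodextrin,1000.0
inulin,1650.0
nacl,58.44
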