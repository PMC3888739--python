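species,toxicant,reason
Salmo gairdneri,Roundup,no regression coefficients printed in the source table
Poecilia reticulata,Methylbenzoate,no regression coefficients printed in the source table
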