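chemical_id,target,call,provenance
tamoxifen,ER,positive,main_text
tamoxifen,AR,inconclusive,main_text
tamoxifen,aromatase,positive,main_text
4-TO,ER,positive,main_text
4-TO,AR,negative,supplementary
4-TO,aromatase,inconclusive,main_text
mestanolone,ER,positive,main_text
mestanolone,AR,positive,main_text
mestanolone,aromatase,negative,main_text
daidzein,ER,positive,main_text
daidzein,AR,inconclusive,main_text
daidzein,aromatase,negative,main_text
BBP,ER,positive,main_text
BBP,AR,inconclusive,main_text
BBP,aromatase,negative,main_text
MBP,ER,negative,main_text
MBP,AR,negative,supplementary
MBP,aromatase,negative,main_text
DEABA,ER,negative,main_text
DEABA,AR,negative,supplementary
DEABA,aromatase,negative,main_text
DBABA,ER,inconclusive,main_text
DBABA,AR,negative,supplementary
DBABA,aromatase,negative,main_text
isoeugenol,ER,inconclusive,main_text
isoeugenol,AR,negative,main_text
isoeugenol,aromatase,negative,main_text
terephthalic_acid,ER,negative,main_text
terephthalic_acid,AR,negative,main_text
terephthalic_acid,aromatase,negative,main_text
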