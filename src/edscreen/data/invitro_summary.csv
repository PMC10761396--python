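chemical_id,assay_id,target,call,ic50_uM,ki_uM,lec_uM,max_effect,note
tamoxifen,yes_agonist,ER,positive,,,,,
tamoxifen,yes_antagonist,ER,positive,,,,,
tamoxifen,yas_agonist,AR,negative,,,,,
tamoxifen,yas_antagonist,AR,negative,,,,,cytotox_masked at highest concentrations; followup_recommended
tamoxifen,er_binding,ER,positive,,,,,
tamoxifen,ar_binding,AR,positive,,,,,
tamoxifen,aromatase,aromatase,negative,,,,,
tamoxifen,calux_er_ag,ER,negative,,,,,
tamoxifen,calux_er_ant,ER,positive,,,0.0011,,assay positive control
tamoxifen,calux_ar_ag,AR,negative,,,,,
tamoxifen,calux_ar_ant,AR,negative,,,,,
tamoxifen,h295r_estrogen,aromatase,negative,,,,,
tamoxifen,h295r_androgen,aromatase,negative,,,,,
4-TO,yes_agonist,ER,positive,,,,,
4-TO,yes_antagonist,ER,negative,,,,,
4-TO,yas_agonist,AR,negative,,,,,
4-TO,yas_antagonist,AR,negative,,,,,cytotox_masked at highest concentrations; followup_recommended
4-TO,er_binding,ER,positive,,,,,
4-TO,ar_binding,AR,positive,27,12,,,significant only at higher concentrations
4-TO,aromatase,aromatase,negative,,,,,
4-TO,calux_er_ag,ER,positive,,,0.04,,
4-TO,calux_er_ant,ER,negative,,,,,
4-TO,calux_ar_ag,AR,negative,,,,,
4-TO,calux_ar_ant,AR,positive,,,0.44,,
4-TO,h295r_estrogen,aromatase,negative,,,,,
4-TO,h295r_androgen,aromatase,negative,,,,,
mestanolone,yes_agonist,ER,positive,,,,,
mestanolone,yes_antagonist,ER,negative,,,,,
mestanolone,yas_agonist,AR,positive,,,,,
mestanolone,yas_antagonist,AR,negative,,,,,
mestanolone,er_binding,ER,positive,1.6,0.52,,,
mestanolone,ar_binding,AR,positive,,,,,
mestanolone,aromatase,aromatase,negative,,,,,
mestanolone,calux_er_ag,ER,positive,,,0.028,,
mestanolone,calux_er_ant,ER,negative,,,,,
mestanolone,calux_ar_ag,AR,positive,,,1.6e-06,,assay reference agonist
mestanolone,calux_ar_ant,AR,negative,,,,,
mestanolone,h295r_estrogen,aromatase,negative,,,,,
mestanolone,h295r_androgen,aromatase,negative,,,,,
daidzein,yes_agonist,ER,positive,,,,,
daidzein,yes_antagonist,ER,negative,,,,,
daidzein,yas_agonist,AR,negative,,,,,
daidzein,yas_antagonist,AR,negative,,,,,
daidzein,er_binding,ER,positive,,,,,
daidzein,ar_binding,AR,negative,,,,,
daidzein,aromatase,aromatase,negative,,,,,
daidzein,calux_er_ag,ER,positive,,,0.1,,
daidzein,calux_er_ant,ER,negative,,,,,
daidzein,calux_ar_ag,AR,negative,,,,,
daidzein,calux_ar_ant,AR,negative,,,,,
daidzein,h295r_estrogen,aromatase,negative,,,,,
daidzein,h295r_androgen,aromatase,positive,,,0.77,0.06,decrease to 0.06-fold of control
BBP,yes_agonist,ER,positive,,,,,
BBP,yes_antagonist,ER,negative,,,,,
BBP,yas_agonist,AR,negative,,,,,
BBP,yas_antagonist,AR,positive,,,,,
BBP,er_binding,ER,positive,0.46,0.15,,69,solubility plateau ~10 uM; relative IC50 at half of own 69% maximum
BBP,ar_binding,AR,weak_positive,,,,,"moderate binding, IC50 > 100 uM"
BBP,aromatase,aromatase,negative,,,,,
BBP,calux_er_ag,ER,positive,,,0.69,,
BBP,calux_er_ant,ER,negative,,,,,
BBP,calux_ar_ag,AR,negative,,,,,
BBP,calux_ar_ant,AR,positive,,,2.4,,weak potency
BBP,h295r_estrogen,aromatase,negative,,,,,
BBP,h295r_androgen,aromatase,negative,,,,,
MBP,yes_agonist,ER,negative,,,,,
MBP,yes_antagonist,ER,positive,,,,,assay false positive vs all other evidence
MBP,yas_agonist,AR,negative,,,,,
MBP,yas_antagonist,AR,negative,,,,,
MBP,er_binding,ER,negative,,,,,
MBP,ar_binding,AR,negative,,,,,
MBP,aromatase,aromatase,negative,,,,,
MBP,calux_er_ag,ER,negative,,,,,
MBP,calux_er_ant,ER,negative,,,,,
MBP,calux_ar_ag,AR,negative,,,,,
MBP,calux_ar_ant,AR,negative,,,,,
MBP,h295r_estrogen,aromatase,negative,,,,,
MBP,h295r_androgen,aromatase,negative,,,,,
DEABA,yes_agonist,ER,negative,,,,,
DEABA,yes_antagonist,ER,inconclusive,,,,,nonspecific_pair
DEABA,yas_agonist,AR,negative,,,,,
DEABA,yas_antagonist,AR,inconclusive,,,,,nonspecific_pair
DEABA,er_binding,ER,negative,,,,,
DEABA,ar_binding,AR,negative,,,,,
DEABA,aromatase,aromatase,negative,,,,,
DEABA,calux_er_ag,ER,weak_positive,,,56,,discrepancy: printed LEC 56 uM vs narrative 10% threshold reached only at 100 uM
DEABA,calux_er_ant,ER,negative,,,,,
DEABA,calux_ar_ag,AR,negative,,,,,
DEABA,calux_ar_ant,AR,negative,,,,,
DEABA,h295r_estrogen,aromatase,negative,,,,,
DEABA,h295r_androgen,aromatase,negative,,,,,
DBABA,yes_agonist,ER,negative,,,,,
DBABA,yes_antagonist,ER,inconclusive,,,,,nonspecific_pair
DBABA,yas_agonist,AR,negative,,,,,
DBABA,yas_antagonist,AR,inconclusive,,,,,nonspecific_pair
DBABA,er_binding,ER,negative,,,,,
DBABA,ar_binding,AR,negative,,,,,
DBABA,aromatase,aromatase,negative,,,,,
DBABA,calux_er_ag,ER,negative,,,,,
DBABA,calux_er_ant,ER,negative,,,,,
DBABA,calux_ar_ag,AR,negative,,,,,
DBABA,calux_ar_ant,AR,negative,,,,,
DBABA,h295r_estrogen,aromatase,negative,,,,,
DBABA,h295r_androgen,aromatase,negative,,,,,
isoeugenol,yes_agonist,ER,negative,,,,,
isoeugenol,yes_antagonist,ER,negative,,,,,
isoeugenol,yas_agonist,AR,negative,,,,,
isoeugenol,yas_antagonist,AR,positive,,,,,
isoeugenol,er_binding,ER,negative,,,,,
isoeugenol,ar_binding,AR,weak_positive,,,,,"moderate binding, IC50 > 100 uM"
isoeugenol,aromatase,aromatase,positive,61,,,,inhibition only at higher concentrations
isoeugenol,calux_er_ag,ER,negative,,,,,
isoeugenol,calux_er_ant,ER,negative,,,,,
isoeugenol,calux_ar_ag,AR,negative,,,,,
isoeugenol,calux_ar_ant,AR,positive,,,0.29,,
isoeugenol,h295r_estrogen,aromatase,positive,,,10,1.5,1.5-fold of control at 100 uM
isoeugenol,h295r_androgen,aromatase,negative,,,,,
terephthalic_acid,yes_agonist,ER,negative,,,,,
terephthalic_acid,yes_antagonist,ER,negative,,,,,
terephthalic_acid,yas_agonist,AR,negative,,,,,
terephthalic_acid,yas_antagonist,AR,negative,,,,,
terephthalic_acid,er_binding,ER,negative,,,,,
terephthalic_acid,ar_binding,AR,negative,,,,,
terephthalic_acid,aromatase,aromatase,negative,,,,,
terephthalic_acid,calux_er_ag,ER,negative,,,,,
terephthalic_acid,calux_er_ant,ER,negative,,,,,
terephthalic_acid,calux_ar_ag,AR,negative,,,,,
terephthalic_acid,calux_ar_ant,AR,negative,,,,,
terephthalic_acid,h295r_estrogen,aromatase,negative,,,,,
terephthalic_acid,h295r_androgen,aromatase,negative,,,,,
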