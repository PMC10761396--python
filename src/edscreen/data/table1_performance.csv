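model_id,target,endpoint_role,pct_correct,pct_efficiency,note
derek,ER,activation,63,100,
derek,AR,activation,71,100,
vega_binding,ER,binding,75,100,
vega_activation,ER,activation,86,88,AR efficiency reconstructed from the narrative list of fully efficient AR models
vega_activation,AR,activation,86,100,AR efficiency reconstructed from the narrative list of fully efficient AR models
vega_aromatase,aromatase,inhibition,78,100,
case_ultra_binding,ER,binding,83,75,
case_ultra_agonist,ER,activation,88,100,
case_ultra_agonist,AR,activation,67,43,
case_ultra_antagonist,ER,antagonist,75,100,
case_ultra_antagonist,AR,antagonist,57,100,
danish_binding,ER,binding,100,100,
danish_binding,AR,binding,100,57,
danish_activation,ER,activation,88,100,
danish_activation,AR,activation,100,86,
danish_antagonist,AR,antagonist,100,57,
admetlab_er_ar,ER,activation,60,63,
admetlab_er_ar,AR,activation,67,86,
admetlab_lbd,ER,binding,88,100,
admetlab_lbd,AR,binding,83,86,
admetlab_aromatase,aromatase,inhibition,100,89,
opera_binding,ER,binding,100,100,
opera_binding,AR,binding,80,71,
opera_agonist,ER,activation,75,100,
opera_agonist,AR,activation,100,86,
opera_antagonist,ER,antagonist,63,100,
opera_antagonist,AR,antagonist,67,86,
admet_predictor_binding,ER,binding,50,100,
admet_predictor_binding,AR,binding,86,100,
endocrine_disruptome_agonist,ER,activation,57,88,
endocrine_disruptome_agonist,AR,activation,100,71,
endocrine_disruptome_antagonist,ER,antagonist,71,88,
endocrine_disruptome_antagonist,AR,antagonist,0,14,
protoxii_er_ar,ER,activation,88,100,
protoxii_er_ar,AR,activation,86,100,
protoxii_lbd,ER,binding,100,100,
protoxii_lbd,AR,binding,86,100,
protoxii_aromatase,aromatase,inhibition,89,100,
admetsar_aromatase,aromatase,inhibition,33,100,oversensitive: the six incorrect calls were all false positives
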