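# Preventive drug classes: relative risks of a first IHD / stroke event with
# treatment (meta-analyses of primary prevention trials; 95% CI bounds kept
# for probabilistic sensitivity analysis) and 2008 A$ annual costs split into
# government (PBS benefit) and patient co-payment components.
# NOTE: the published beta-blocker confidence intervals (0.89-1.02 for IHD,
# 0.83-0.99 for stroke) do not bracket their printed means (0.78, 0.70); the
# means are used as printed and the lnRR standard error is taken from the
# absolute CI width.  The beta-blocker cost row's published source note also
# repeats the statin drug list (an apparent copy error in the source table);
# the printed prices are used as-is.
name,rr_ihd,rr_ihd_lo,rr_ihd_hi,rr_stroke,rr_stroke_lo,rr_stroke_hi,annual_cost_gov,annual_cost_patient
statin,0.70,0.61,0.81,0.81,0.71,0.93,508.64,178.79
diuretic,0.86,0.75,0.98,0.62,0.53,0.72,52.03,18.79
calcium_channel_blocker,0.85,0.78,0.92,0.66,0.58,0.75,163.66,54.22
ace_inhibitor,0.83,0.78,0.89,0.78,0.66,0.92,130.85,81.21
beta_blocker,0.78,0.89,1.02,0.70,0.83,0.99,169.59,47.09
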