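# GP visit and blood test costs attached to preventive drug treatment,
# 2008 A$ unit prices (MBS Level C / Level B consultations, item 66512
# pathology) with annual unit counts by treatment pattern and year.
# pattern: lipid = lipid drugs only, bp = blood pressure drugs only,
# both = combined lipid + blood pressure treatment.
pattern,item,unit_price_gov,unit_price_patient,units_year1,units_later
lipid,long_gp_visit,54.19,9.56,1,0
lipid,short_gp_visit,28.52,5.03,0,2
lipid,blood_test,15.13,2.67,1,2
bp,long_gp_visit,54.19,9.56,1,0
bp,short_gp_visit,28.52,5.03,2,2
bp,blood_test,15.13,2.67,3,2
both,long_gp_visit,54.19,9.56,1,0
both,short_gp_visit,28.52,5.03,2,2
both,blood_test,15.13,2.67,4,2
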