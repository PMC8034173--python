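study_label,registry_id,comparison,endpoint_label,endpoint_rank,exp_total,exp_events,ctrl_total,ctrl_events,reported_p,allocation_ratio
SILIUS,NCT01214343,Sorafenib plus HAIC vs. sorafenib,Overall response,primary,102,37,103,18,0.003,1:1
Wang Z,NCT01966133,Adjuvant TACE vs. no adjuvant TACE,Recurrence-free survival,primary,140,46,140,82,0.011,1:1
Lee JH,NCT00699816,CIK cell agent vs. no CIK cell agent,Recurrence-free survival,primary,114,69,112,59,0.01,1:1
SHARP,NCT00105443,Sorafenib vs. placebo,Overall survival,primary,299,44,303,33,0.00583,1:1
Wei W,NCT02788526,Hepatectomy plus TACE vs. hepatectomy,Disease-free survival,primary,116,83,118,85,0.02,1:1
Geissler EK,NCT0035586,Liver transplantation with sirolimus vs. liver transplantation,Overall survival,secondary,252,242,256,234,,1:1
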