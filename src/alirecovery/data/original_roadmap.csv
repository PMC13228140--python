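component,term,provenance
SBP,Hypertension,original
DBP,Hypertension,original
BMI,Obesity,original
BMI,Morbid obesity,original
BMI,"Grade I, II, or III obesity",original
TRIG,Hypertriglyceridemia,original
CHOL,Hypercholesterolemia,original
CRP,Sepsis,original
CRP,infection,original
CRP,Auto-immune inflammatory syndrome,original
HBA1C,Diabetes,original
HBA1C,Impaired glycemic control,original
CC,Renal failure,original
CC,Insufficiency,original
CC,Acute kidney injury,original
CC,Chronic renal failure,original
HCST,Hyperhomocysteinemia,original
HCST,Vitamin deficiency,original
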