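# Clinical thresholds defining the unhealthy range for each allostatic load
# index component.  direction is the comparison that makes a value UNHEALTHY.
# Creatinine clearance is the only sex-specific rule.  The serum-albumin
# direction is implemented exactly as printed in the source threshold table
# (>= 3.5), although low albumin is the conventional risk direction; see
# docs/methods.md.
SBP:   {direction: greater,       cutoff: 140,  units: mmHg}
DBP:   {direction: greater,       cutoff: 90,   units: mmHg}
BMI:   {direction: greater,       cutoff: 30,   units: kg/m^2}
TRIG:  {direction: greater_equal, cutoff: 150,  units: mg/dL}
CHOL:  {direction: greater_equal, cutoff: 200,  units: mg/dL}
CRP:   {direction: greater_equal, cutoff: 10,   units: mg/L}
HBA1C: {direction: greater_equal, cutoff: 6.5,  units: "%"}
ALB:   {direction: greater_equal, cutoff: 3.5,  units: g/dL}
CC:    {direction: less,          cutoff: {male: 110, female: 100}, units: mL/min}
HCST:  {direction: greater,       cutoff: 50,   units: umol/L}
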