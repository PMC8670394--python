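name,description
pH,Acidity
pO2,Oxygen partial pressure
pCO2,Carbon dioxide partial pressure
ABE,Excess base
SBE,Lack of reason
cHCO3,Plasma bicarbonate
cHCO3-st,Bicarbonate (alkali)
sO2,Oxygen boost
ctHb,Reference hemoglobin level
Htc,Hematocrit
K+,Potassium ion concentration
Na+,Sodium ion concentration
Ca++,Calcium ion concentration
Cl-,Chlorine ion concentration
Glu,Glucose concentration
Lac,Lactate content
p50,Hemoglobin affinity for oxygen
mOsm,Blood osmolarity
pH(T),Acidity corrected for temperature
pO2(T),Partial oxygen pressure adjusted for temperature
pCO2(T),Carbon dioxide partial pressure adjusted for temperature
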