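drug,group
lisinopril,acei_arb
ramipril,acei_arb
losartan,acei_arb
bisoprolol,beta_blocker
carvedilol,beta_blocker
furosemide,diuretic
hydrochlorothiazide,diuretic
digoxin,digoxin
spironolactone,mra
eplerenone,mra
warfarin,anticoagulant
apixaban,anticoagulant
aspirin,antiplatelet
clopidogrel,antiplatelet
atorvastatin,statin
simvastatin,statin
salbutamol,bronchodilator
tiotropium,bronchodilator
ferrous-sulfate,hematinic
darbepoetin,hematinic
oxybutynin,anticholinergic
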