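# 28 drugs used for the drug-event visualization statistics
anesthesia
antihistamine
antipsychotic
aspirin
atenolol
atorvastatin
azithromycin
dexamethasone
diazepam
dopamine
ephedrine
gabapentin
galantamine
heparin
ibuprofen
lamotrigine
lorazepam
melatonin
meloxicam
metformin
methylphenidate
ondansetron
orlistat
sildenafil
statins
vioxx
warfarin
wellbutrin
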