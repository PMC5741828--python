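# Small curated adverse-event vocabulary (synthetic fixture; user lexicons
# can replace it). Lower-cased, multi-word terms allowed.
hypotension
nausea
aspiration
depression
dizziness
fatigue
edema
diarrhea
vomiting
stomach pain
bradycardia
tiredness
myopathy
rhabdomyolysis
myalgia
hepatic dysfunction
impotence
bleeding
lactic acidosis
weight gain
drowsiness
seizure
headache
rash
insomnia
constipation
dry mouth
anxiety
tremor
palpitations
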