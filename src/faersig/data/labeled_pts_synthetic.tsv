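pt	note
NAUSEA	synthetic stand-in label list for unlisted-event detection
DIARRHOEA	synthetic
VOMITING	synthetic
ABDOMINAL PAIN UPPER	synthetic
ABDOMINAL PAIN	synthetic
ABDOMINAL DISTENSION	synthetic
ABDOMINAL DISCOMFORT	synthetic
DYSPEPSIA	synthetic
GASTROOESOPHAGEAL REFLUX DISEASE	synthetic
FLATULENCE	synthetic
CONSTIPATION	synthetic
HEADACHE	synthetic
DIZZINESS	synthetic
FATIGUE	synthetic
URTICARIA	synthetic
RASH	synthetic
PRURITUS	synthetic
HYPERTENSION	synthetic
URINARY TRACT INFECTION	synthetic
NASOPHARYNGITIS	synthetic
HYPOMAGNESAEMIA	synthetic
BLOOD GASTRIN INCREASED	synthetic
GASTRIC POLYPS	synthetic
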