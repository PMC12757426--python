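pt	soc
NAUSEA	GASTROINTESTINAL DISORDERS
DIARRHOEA	GASTROINTESTINAL DISORDERS
VOMITING	GASTROINTESTINAL DISORDERS
ABDOMINAL PAIN UPPER	GASTROINTESTINAL DISORDERS
ABDOMINAL DISTENSION	GASTROINTESTINAL DISORDERS
ABDOMINAL DISCOMFORT	GASTROINTESTINAL DISORDERS
DYSPEPSIA	GASTROINTESTINAL DISORDERS
GASTROOESOPHAGEAL REFLUX DISEASE	GASTROINTESTINAL DISORDERS
FLATULENCE	GASTROINTESTINAL DISORDERS
HAEMATEMESIS	GASTROINTESTINAL DISORDERS
COLITIS MICROSCOPIC	GASTROINTESTINAL DISORDERS
GASTRIC POLYPS	GASTROINTESTINAL DISORDERS
GASTROINTESTINAL POLYP HAEMORRHAGE	GASTROINTESTINAL DISORDERS
DUODENAL ULCER	GASTROINTESTINAL DISORDERS
GASTRIC MUCOSAL HYPERTROPHY	GASTROINTESTINAL DISORDERS
FAECES DISCOLOURED	GASTROINTESTINAL DISORDERS
ERUCTATION	GASTROINTESTINAL DISORDERS
HYPERGASTRINAEMIA	GASTROINTESTINAL DISORDERS
OESOPHAGITIS	GASTROINTESTINAL DISORDERS
GASTROINTESTINAL PAIN	GASTROINTESTINAL DISORDERS
GASTRITIS	GASTROINTESTINAL DISORDERS
OESOPHAGEAL DISORDER	GASTROINTESTINAL DISORDERS
OESOPHAGEAL PAIN	GASTROINTESTINAL DISORDERS
GASTRIC HAEMORRHAGE	GASTROINTESTINAL DISORDERS
GASTRIC ULCER	GASTROINTESTINAL DISORDERS
PARAESTHESIA ORAL	GASTROINTESTINAL DISORDERS
GASTRIC ULCER HAEMORRHAGE	GASTROINTESTINAL DISORDERS
MALABSORPTION	GASTROINTESTINAL DISORDERS
HIATUS HERNIA	GASTROINTESTINAL DISORDERS
VARICOSE VEIN	VASCULAR DISORDERS
STEVENS-JOHNSON SYNDROME	SKIN AND SUBCUTANEOUS TISSUE DISORDERS
RASH	SKIN AND SUBCUTANEOUS TISSUE DISORDERS
PRURITUS	SKIN AND SUBCUTANEOUS TISSUE DISORDERS
THROAT IRRITATION	RESPIRATORY, THORACIC AND MEDIASTINAL DISORDERS
THROAT TIGHTNESS	RESPIRATORY, THORACIC AND MEDIASTINAL DISORDERS
DRY THROAT	RESPIRATORY, THORACIC AND MEDIASTINAL DISORDERS
DYSPNOEA	RESPIRATORY, THORACIC AND MEDIASTINAL DISORDERS
RENAL IMPAIRMENT	RENAL AND URINARY DISORDERS
NEAR DEATH EXPERIENCE	PSYCHIATRIC DISORDERS
INSOMNIA	PSYCHIATRIC DISORDERS
DEMENTIA	NERVOUS SYSTEM DISORDERS
FACIAL PARALYSIS	NERVOUS SYSTEM DISORDERS
HEADACHE	NERVOUS SYSTEM DISORDERS
DIZZINESS	NERVOUS SYSTEM DISORDERS
GASTRIC CANCER	NEOPLASMS BENIGN, MALIGNANT AND UNSPECIFIED (INCL CYSTS AND POLYPS)
OESOPHAGEAL ADENOCARCINOMA	NEOPLASMS BENIGN, MALIGNANT AND UNSPECIFIED (INCL CYSTS AND POLYPS)
NEUROENDOCRINE TUMOUR	NEOPLASMS BENIGN, MALIGNANT AND UNSPECIFIED (INCL CYSTS AND POLYPS)
MUSCULOSKELETAL DISCOMFORT	MUSCULOSKELETAL AND CONNECTIVE TISSUE DISORDERS
SJOGREN'S SYNDROME	MUSCULOSKELETAL AND CONNECTIVE TISSUE DISORDERS
ARTHRALGIA	MUSCULOSKELETAL AND CONNECTIVE TISSUE DISORDERS
HYPOMAGNESAEMIA	METABOLISM AND NUTRITION DISORDERS
BLOOD GASTRIN INCREASED	INVESTIGATIONS
BLOOD MAGNESIUM DECREASED	INVESTIGATIONS
BLOOD PRESSURE DECREASED	INVESTIGATIONS
WEIGHT INCREASED	INVESTIGATIONS
OESOPHAGEAL CANDIDIASIS	INFECTIONS AND INFESTATIONS
CHOLECYSTITIS	HEPATOBILIARY DISORDERS
THIRST	GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS
POLYP	GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS
ASTHENIA	GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS
FATIGUE	GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS
ILLNESS	GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS
PALPITATIONS	CARDIAC DISORDERS
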