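icd10	phecode	label
E20	252.2	Hypoparathyroidism
E208	252.2	Other hypoparathyroidism
E209	252.2	Hypoparathyroidism, unspecified
E835	275.5	Disorders of calcium metabolism
E833	275.5	Disorders of phosphorus metabolism
R290	350.1	Tetany
R202	687.4	Paresthesia of skin
G40	345.1	Epilepsy
G400	345.11	Localization-related idiopathic epilepsy
G403	345.12	Generalized idiopathic epilepsy
G409	345.1	Epilepsy, unspecified
I10	401.1	Essential hypertension
E119	250.2	Type 2 diabetes
J459	495	Asthma
K210	530.11	GERD with esophagitis
M545	760	Low back pain
F329	296.2	Depression
N390	591	Urinary tract infection
E780	272.1	Hypercholesterolemia
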