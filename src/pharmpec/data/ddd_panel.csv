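api_name,atc_code,ddd_value_g,route
paracetamol,N02AJ06,3.0,oral
paracetamol,N02BE01,3.0,oral
paracetamol,N02BE51,3.0,oral
ibuprofen,M02AA13,,
ibuprofen,C01EB16,0.03,oral
ibuprofen,M01AE01,1.2,oral
xylometazoline,R01AA07,0.0008,nasal
xylometazoline,R01AB06,,
amoxicillin,J01CA04,1.5,oral
amoxicillin,J01CA04,3,injected
amoxicillin,J01CR02,1.5,oral
amoxicillin,J01CR02,3,injected
amoxicillin,QJ01CA04,,
progesterone,G03DA04,0.03,oral
progesterone,G03DA04,0.005,injected
progesterone,G03DA04,0.09,vaginal
progesterone,QG03DA04,,
atorvastatin,C10AA05,0.02,oral
atorvastatin,C10BA05,,
metoprolol,C07AB02,0.15,oral
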