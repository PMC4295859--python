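set	category	setting	direction	fdr_q	p_nominal
Adherens junction	Cellular Processes; Cell Communication	cisplatin_acute	down	0.07	0.003
Focal adhesion	Cellular Processes; Cell Communication	cisplatin_acute	down	0.04	<0.0001
p53 signalling pathway	Cellular Processes; Cell Growth and Death	bleomycin_acute	up	0.001	<0.0001
p53 signalling pathway	Cellular Processes; Cell Growth and Death	cisplatin_acute	up	0.02	<0.0001
p53 signalling pathway	Cellular Processes; Cell Growth and Death	cisplatin_chronic	down	0.1	<0.0001
TGF-beta signalling pathway	Environmental Information Processing; Signal Transduction	cisplatin_acute	down	0.05	<0.0001
Ubiquitin mediated proteolysis	Genetic Information Processing; Folding, Sorting and Degradation	cisplatin_acute	down	0.04	0.001
Endometrial cancer	Human Diseases	cisplatin_acute	down	0.04	<0.0001
Cholera infection	Human Diseases	bleomycin_acute	up	0.10	0.005
Type I Diabetes Mellitus	Human Diseases	bleomycin_acute	up	0.07	<0.0001
Type I Diabetes Mellitus	Human Diseases	cisplatin_acute	up	0.05	<0.0001
Type I Diabetes Mellitus	Human Diseases	cisplatin_chronic	down	0.01	<0.0001
Neurodegerative disease	Human Diseases	cisplatin_chronic	down	0.09	0.008
Prion diseases	Human Diseases	cisplatin_chronic	down	0.08	0.01
Butanoate metabolism	Metabolism; Carbohydrate Metabolism	bleomycin_acute	up	0.02	<0.0001
Glyoxylate and dicarboxylate metabolism	Metabolism; Carbohydrate Metabolism	cisplatin_acute	down	0.09	0.02
Reductive carboxylate cycle	Metabolism; Carbohydrate Metabolism	cisplatin_acute	down	0.04	0.002
Glycosylphosphatidylinositol(GPI)-anchor biosynthesis	Metabolism; Carbohydrate Metabolism	bleomycin_acute	up	0.03	0.002
N-Glycan biosynthesis	Metabolism; Carbohydrate Metabolism	cisplatin_acute	down	0.08	<0.0001
Linoleic acid metabolism	Metabolism; Carbohydrate Metabolism	bleomycin_acute	up	0.08	0.005
Linoleic acid metabolism	Metabolism; Carbohydrate Metabolism	cisplatin_acute	up	0.09	0.01
Polyunsatyrated fatty acid biosynthesis	Metabolism; Carbohydrate Metabolism	cisplatin_acute	down	0.04	0.002
Antigen processing and presentation	Organismal Systems; Immune System	cisplatin_chronic	down	0.0	<0.0001
Toll-like receptor signalling pathway	Organismal Systems; Immune System	cisplatin_chronic	down	0.08	<0.0001
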