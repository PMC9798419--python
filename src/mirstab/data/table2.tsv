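feature_id	lower	upper	AML	Biliary	CLL	Colorectal	Early_colon	Gastric	Lung_adenocarcinoma	Nasopharyngeal	Pancreatic	Prostate	ALL
miR-142-3p	-0.622	0.510	-1.491	-0.840	0.519	-0.773	-0.782	2.796	-1.678	0.296	-0.687	-0.792	1.697
miR-199a-5p	-0.111	0.114	2.240	-2.165	-3.271	-0.899	-0.333	1.069	-2.151	2.906	-1.070	-0.679	0.432
miR-223-5p	-0.326	0.278	-1.924	2.470	-0.004	-0.386	-0.042	1.550	0.968	1.684	1.496	-0.333	3.024
let-7d-5p	-0.263	0.426	0.623	-0.435	-0.967	-0.676	0.559	1.473	-0.876	0.162	-0.222	-0.271	-0.623
miR-148b-3p	-0.097	0.112	0.005	-0.834	-1.409	-0.666	-0.233	-0.841	-1.400	1.248	-0.675	-0.135	0.592
miR-340-5p	-0.143	0.258	-2.075	1.286	0.533	0.169	-1.467	-0.769	-1.948	1.525	0.915	-0.080	2.611
miR-421	-0.354	0.317	-0.452	1.276	-1.172	0.368	-0.885	-1.709	-0.680	0.441	0.990	-0.083	-0.533
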