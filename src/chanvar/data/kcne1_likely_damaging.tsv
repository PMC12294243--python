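variant	cs	functional_study	clinpred	paralogue_evidence
S28L	0.6	Smaller current	0.818	KCNE5-VUS:D44H
R32C	0.8	faster activation	0.622	KCNE3-VUS:R47G;KCNE3-VUS:R47Q;KCNE3-VUS:R47W
P35S	0.4	faster activation	0.957	KCNE2-VUS:V41A
L48I	0.9	~ current	0.963	KCNE2-Disease:M54T;KCNE2-VUS:M54V
L48F	0.9	faster activation	0.808	KCNE2-Disease:M54T;KCNE2-VUS:M54V
L48P	0.9		0.999	KCNE2-Disease:M54T;KCNE2-VUS:M54V
M49T	0.7		0.958	KCNE5-VUS:L65F
F53L	0.8	~ current	0.756	KCNE2-VUS:M59I;KCNE5-VUS:F69V
F53C	0.8	Small current	0.996	KCNE2-VUS:M59I;KCNE5-VUS:F69V
G55R	0.8		0.994	KCNE2-VUS:S61P
T58P	0.6	Slower activation	0.982	NA-Disease:T58P;KCNE3-VUS:V72G
T58A	0.6		0.987	NA-Disease:T58P;KCNE3-VUS:V72G
L59P	0.7	LoF	0.978	KCNE2-VUS:V65L;KCNE2-VUS:V65M;KCNE5-VUS:G75R
G60D	0.8	Small current	0.994	KCNE2-VUS:A66V;KCNE3-VUS:S74R;KCNE5-VUS:G76D
G60V	0.8		0.995	KCNE2-VUS:A66V;KCNE3-VUS:S74R;KCNE5-VUS:G76D
I61F	1		0.983	KCNE2-VUS:I67M
I66L	0.7		0.905	KCNE3-VUS:T80I
R67G	0.9	Small current	0.996	KCNE3-VUS:R81C
R67S	0.9	Small current	0.987	KCNE3-VUS:R81C
R67L	0.9	Small current	0.99	KCNE3-VUS:R81C
R67H	0.9	Small current	0.873	KCNE3-VUS:R81C
K69E	0.9		0.953	KCNE3-VUS:R83C;KCNE3-VUS:R83P;KCNE5-VUS:R85H
K70Q	0.9		0.977	KCNE3-VUS:K84E;KCNE5-VUS:K86E
K70M	0.9	Small current	0.994	KCNE3-VUS:K84E;KCNE5-VUS:K86E
K70E	0.9		0.983	KCNE3-VUS:K84E;KCNE5-VUS:K86E
L71V	0.4		0.956	KCNE2-Disease:R77W;KCNE3-VUS:V85A
E72K	0.4		0.984	KCNE5-VUS:V88D;KCNE5-VUS:V88I
H73R	0.6		0.931	KCNE2-VUS:H79R;KCNE5-VUS:E89K
S74W	0.4	Small current	0.998	KCNE2-VUS:S80P;KCNE3-VUS:R88C;KCNE3-VUS:R88H
S74P	0.4	Smaller current	0.629	KCNE2-VUS:S80P;KCNE3-VUS:R88C;KCNE3-VUS:R88H
Y81C	0.7	Smaller current	0.998	KCNE2-VUS:Y87C
I82M	0.4	Smaller current	0.885	KCNE3-VUS:I96S
I82V	0.4	Smaller current	0.978	KCNE3-VUS:I96S
I82F	0.4		0.993	KCNE3-VUS:I96S
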