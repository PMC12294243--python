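plic_label	variant	paralogue_evidence	clinpred	alphamissense	current_change
1.532	E115D	KCNQ2-E86K	0.878	0.997	
1.545	A128P	KCNQ2-Y98X	0.185	0.861	
1.548	L131P	KCNQ2-L101H	0.995	0.958	strong_decrease
1.550	V133A	KCNA1-I177N;KCNB1-I199F;KCNQ2-V103D	0.984	0.964	moderate_decrease
1.553	C136F	KCNQ2-C106G	1	0.954	strong_decrease
1.554	L137P	KCNQ2-L107F	0.986	0.999	
1.557	S140R	KCNA1-F184C	0.996	0.999	strong_decrease
1.560	S143F	KCNB1-N209K	0.997	0.953	
2.544	V164A	KCNQ2-I134N	0.998	0.797	
2.550	E170G	KCNQ2-E140A	1	0.987	
2.551	Y171H	KCNV2-Y317X	0.998	0.998	
2.556	W176S	KCNQ2-W146X	1	0.926	
2.609	G189A	KCNQ2-G159E/R/V	0.998	0.978	strong_decrease
3.549	I201V	KCNA2-I258N	0.944	0.507	
3.550	D202V	KCNQ2-D172G	1	0.998	
3.560	V212A	KCNQ2-V182M	0.994	0.958	
3.560	V212F	KCNQ2-V182M	0.997	0.917	
3.600	G219E	KCNA1-E283K;KCNQ2-G189D	0.989	0.817	
4.542	A223T	KCNQ2-A193D/V	0.994	0.772	
4.547	R228W	KCNA2-R294H;KCNQ2-R198W	1	0.966	
4.553	Q234L	KCNA2-R300S;KCNB1-R303Q;KCNC3-R420H;KCNQ2-Q204H	0.998	0.965	
4.553	Q234R	KCNA2-R300S;KCNB1-R303Q;KCNC3-R420H;KCNQ2-Q204H	0.97	0.992	
4.558	L239V	KCNQ2-I209S/T	0.829	0.86	
4.559	H240R	KCNQ2-R210C/H/P	0.331	0.949	
4.559	H240Q	KCNQ2-R210C/H/P	0.993	0.991	
5.518	G245R	KCND3-S304F	0.998	0.998	strong_decrease
5.523	L250P	KCNA1-I314T;KCNB1-S319F/Y	0.995	1	
5.525	G252R	KCNB1-G321S	1	0.996	
5.525	G252S	KCNB1-G321S	0.998	0.885	
5.526	S253A	KCNQ2-S223F/P	0.972	0.792	
5.530	I257S	KCNQ2-A227V	0.993	0.947	
5.533	Q260H	KCNQ2-K230M	0.991	0.99	
5.535	L262V	KCNC3-F448L	0.996	0.952	
5.536	I263K	KCNB1-G332V	0.997	0.997	
5.537	T264S	KCNQ2-T234A/P	0.992	0.895	
5.540	Y267F	KCNQ2-Y237C	0.996	0.644	
5.541	I268V	KCNC2-F388S	0.878	0.674	
5.548	F275L	KCNQ2-L245P	0.996	0.986	
5.552	F279C	KCND3-V338E;KCNQ2-L249P	0.999	0.788	
5.556	A283T	KCNQ2-A253S/T	0.996	0.504	
5.557	E284G	KCNQ2-E254D	1	0.972	
5.613	S298R	KCNQ2-T263A/I	0.997	0.977	
5.837	A300G	KCNQ2-A265P/T/V	0.986	0.747	
5.843	G306E	KCNQ2-G271D/R/S/V;KCNQ3-G310D/V	0.999	0.999	
5.844	V307M	KCNB1-T372N/I	0.991	0.79	
5.844	V307L	KCNB1-T372N/I	0.99	0.895	
5.844	V307E	KCNB1-T372M/I	0.993	0.989	
5.849	T312S	KCNA2-T374A;KCNC2-T437A;KCNQ2-T277N/P/S	0.995	0.966	
5.850	I313F	KCNQ2-I278F/M/T;KCNQ3-I317M/T	0.993	0.991	
5.855	K318N	KCNQ2-K283E	0.958	0.93	
5.856	V319M	KCNQ2-Y284C/D	0.995	0.616	
6.543	A329V	KCND3-G384S;KCNQ2-A294G/S	0.999	0.979	
6.543	A329T	KCND3-G384S;KCNQ2-A294G/S	0.987	0.935	
6.544	S330Y	KCND3-S385P	0.998	0.993	
6.545	C331Y	KCNQ2-T296P	0.998	0.976	
6.549	F335C	KCNA1-A395S	0.997	0.856	
6.551	I337M	KCNA2-V399M	0.962	0.775	
6.553	F339V	KCNQ2-F304C;KCNQ2-F304S	0.999	0.972	
6.555	A341T	KCNA1-A401V;KCNB1-A406V;KCNQ2-A306P/T/V/E	0.996	0.976	
6.563	S349A	KCNB1-N414D	0.995	0.92	
6.563	S349L	KCNB1-N414D	0.999	0.995	
6.566	A352P	KCNB1-S417P;KCNQ2-A317T;KCNQ3-A356T	0.999	0.997	
6.566	A352D	KCNB1-S417P;KCNQ2-A317T;KCNQ3-A356T	0.998	1	
6.569	K354R	KCNQ2-K319E	0.992	0.768	
6.571	Q357R	KCNA1-R417X;KCNB1-E422A	0.996	0.984	
6.571	Q357E	KCNA1-R417X;KCNB1-E422A	0.939	0.566	
6.574	R360T	KCNQ2-R325G;KCNQ3-R364C/H	0.999	0.999	
6.574	R360K	KCNQ2-R325G;KCNQ3-R364C/H	0.992	0.976	
7.013	L374V	KCNQ2-L339Q;KCNQ2-L339R	0.995	0.85	
7.030	T391P	KCNQ2-T359K	0.998	0.898	
7.165	K526E	KCNQ2-K552N	0.932	0.967	
7.165	K526Q	KCNQ2-K552N	0.838	0.717	
7.165	K526N	KCNQ2-K552N	0.984	0.995	
7.180	V541I	KCNQ2-V567D	0.903	0.814	
7.187	G548D	KCNQ2-G574D/S	0.999	0.999	
7.194	R555L	KCNQ2-R581G	0.998	0.994	
7.196	K557R	KCNQ2-K583N	0.982	0.63	
7.222	R583S	KCNQ2-K606X	0.885	0.902	
7.222	R583G	KCNQ2-K606X	0.79	0.606	
7.230	R591P	KCNQ2-R622P	0.997	0.997	
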