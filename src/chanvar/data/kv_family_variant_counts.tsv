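gene	uniprot_acc	n_plp	n_vus	n_neutral
KCNA1	Q09470	38	245	14
KCNA2	P16389	44	207	10
KCNA5	P22460	4	276	56
KCNB1	Q14721	87	212	62
KCNC1	P48547	11	149	11
KCNC2	Q96PR1	12	44	37
KCNC3	Q14003	10	173	82
KCND2	Q9NZV8	7	176	22
KCND3	Q9UK17	21	207	17
KCNQ1	P51787	299	519	43
KCNQ2	O43526	394	474	57
KCNQ3	O43525	39	458	49
KCNQ4	P56696	28	153	63
KCNQ5	Q9NR82	20	228	65
KCNV2	Q8TDN2	45	361	103
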