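name	index	protein_pos	msa_col	region
EnSpm12_Fves	1	462	564	G
C	1	718	771	I
EnSpm10_Fves	1	826	846	.
Joey	1	842	893	II
Janus	1	837	894	II
F	1	846	894	II
G	1	847	894	II
Norman	1	879	921	III
En1	1	879	925	III
Alfred	1	885	925	III
H	1	838	972	.
EnSpm3_Vvin	1	821	894	II
EnSpm3_Vvin	2	856	925	III
EnSpm8_Sbic	1	754	783	I
EnSpm8_Sbic	2	976	0	.
Storm	1	827	782	I
Storm	2	951	0	.
Sherman	1	831	782	I
Sherman	2	954	0	.
J	1	495	521	.
J	2	750	885	.
EnSpm2_Mdom	1	755	782	I
EnSpm2_Mdom	2	886	893	II
Baldur	1	731	782	I
Baldur	2	837	895	II
I	1	834	782	I
I	2	954	910	.
Isidor	1	857	894	II
Isidor	2	892	920	III
Radon	1	841	894	II
Radon	2	877	921	III
Rufus	1	851	894	II
Rufus	2	887	921	III
EnSpm13_Vvin	1	821	894	II
EnSpm13_Vvin	2	856	925	III
EnSpm5_Vvin	1	824	894	II
EnSpm5_Vvin	2	859	925	III
Isaac	1	861	894	II
Isaac	2	900	925	III
Sandro	1	744	782	I
Sandro	2	851	928	III
Balduin	1	850	895	II
Balduin	2	890	930	III
DOPPIA	1	843	894	II
DOPPIA	2	890	936	III
K	1	744	782	I
K	2	850	936	III
Horace	1	712	711	.
Horace	2	981	1054	.
EnSpm4_Fves	1	812	0	.
EnSpm4_Fves	2	992	0	.
EnSpm4_Fves	3	1244	0	.
EnSpm3_Fves	1	681	0	.
EnSpm3_Fves	2	770	781	I
EnSpm3_Fves	3	919	0	.
Seamus	1	730	782	I
Seamus	2	833	892	II
Seamus	3	878	925	III
Dario	1	726	711	.
Dario	2	842	839	.
Dario	3	895	890	III
Aron	1	851	833	.
Aron	2	899	879	II
Aron	3	1013	1060	.
Korbin	1	510	567	G
Korbin	2	718	782	I
Korbin	3	814	894	II
Korbin	4	853	0	.
Chester	1	520	563	G
Chester	2	728	777	I
Chester	3	823	889	II
Chester	4	858	920	III
Baron	1	522	568	G
Baron	2	730	781	I
Baron	3	825	893	II
Baron	4	861	925	III
EnSpm8_Fves	1	158	163	.
EnSpm8_Fves	2	830	893	II
EnSpm8_Fves	3	975	0	.
EnSpm8_Fves	4	1219	0	.
EnSpm8_Fves	5	1500	0	.
ATENSPM6_Athal	1	802	809	.
ATENSPM6_Athal	2	918	922	III
ATENSPM6_Athal	3	978	981	.
ATENSPM6_Athal	4	1011	1012	.
ATENSPM6_Athal	5	1141	0	.
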