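uniprot	agi_locus	functional_category	ratio
Q08466	AT3G50000	Signalling	2.8638
Q9SRQ7	AT3G03530	Signalling	3.2845
Q8VZG1	AT2G18730	Signalling	2.1248
P25071	At2G41100	Signalling	3.679
O48917	AT4G33030	Lipid metabolism	2.1263
Q8L5Z1	AT1G33811	Lipid metabolism	2.5715
Q8LPS1	At3G05970	Lipid metabolism	2.7547
Q9M7Z1	AT3G06850	Lipid metabolism	1.7488
Q9SJD4	At2G04350	Lipid metabolism	1.7513
P50700	AT4G11650	Stress Defence	2.4094
Q06327	AT1G55020	Stress Defence	4.1369
Q683G1		Stress Defence	2.1047
Q8VZG8	AT4G08850	Stress Defence	2.9398
Q941L3	AT5G61900	Stress Defence	1.7347
Q94AJ8		Stress Defence	2.3775
Q9LSP5	AT3G17020	Stress Defence	1.9398
Q9SRH6	AT3G01290	Stress Defence	2.7526
Q1EBW2	AT5G19550	Amino-acid synthesis	1.7205
Q9SZJ5	AT4G37930	Amino-acid synthesis	1.512
O22773	AT4G02530	Chloroplast	1.5287
Q1H537	AT5G18660	Chloroplast	1.9528
Q2HIV2	AT3G25760	Chloroplast	3.8866
Q9FYC2	AT3G44880	Chloroplast	2.5419
Q9LW57	AT3G23400	Chloroplast	1.4798
O49607	AT4G34980	Proteases	1.7715
Q9STL8	AT3G48380	Proteases	1.9345
O04551	AT1G27020	Unknown	2.1419
O04616	AT4G01150	Unknown	2.3716
O23601		Unknown	1.8203
Q8H0W8		Unknown	1.9158
Q8VYV1		Unknown	2.3485
Q93VA8	AT1G76010	Unknown	1.7247
Q93W02	AT5G24690	Unknown	1.9446
Q94CD9		Unknown	1.7983
Q9LIL4	AT3G22845	Unknown	2.9425
Q9LTB7		Unknown	2.1824
Q9LVM3	AT5G58250	Unknown	2.2543
Q9M1J1	AT3G57090	Unknown	2.1494
Q9SH90		Unknown	1.7123
P57106	AT5G43330	Tricarboxylic cycle	2.0606
Q94A28	AT4G26970	Tricarboxylic cycle	1.7543
P38418	AT3G45140	Hormone biosynthesis	2.8506
Q9LS02	AT3G25770	Hormone biosynthesis	2.961
Q9M0X9	AT4G05160	Hormone biosynthesis	1.7386
B9DHS6		Miscellaneous	2.0934
Q38924	AT2G27190	Miscellaneous	2.2812
Q56WN1	AT5G37600	Miscellaneous	2.0578
Q94AF6	AT5G20160	Miscellaneous	2.9457
Q9FVQ1	AT1G48920	Miscellaneous	1.781
Q9LSE4	AT3G26710	Miscellaneous	1.8275
Q9M5P3	AT5G54290	Miscellaneous	2.3778
Q9SIV9	AT2G16430	Miscellaneous	1.8662
Q9SR40	AT3G09220	Miscellaneous	2.1287
Q9SRT9	AT3G02230	Miscellaneous	2.2652
Q9SX77	AT1G47420	Miscellaneous	1.7168
Q9ZVA2	AT1G78830	Miscellaneous	1.9959
A8MRC4	AT1G30230	Protein synthesis	2.435
Q9FVT2	AT1G57720	Protein synthesis	2.0131
Q9SCX3	AT5G19510	Protein synthesis	3.4476
Q84WU9	AT5G56900	Transcription	2.0231
Q9SRM4	AT3G11200	Transcription	1.8897
B1GV36		Oxydoreduction	3.5288
O49340		Oxydoreduction	2.7992
O65782	AT4G31500	Oxydoreduction	1.879
O65787	AT2G24180	Oxydoreduction	2.0196
O80852	AT2G30860	Oxydoreduction	1.7945
O81816	AT4G38540	Oxydoreduction	2.2396
Q94BV7	AT4G05020	Oxydoreduction	2.4173
Q9SMU8	AT3G49120	Oxydoreduction	7.3136
Q9SRY5	AT1G02920	Oxydoreduction	4.6163
Q9SU63	AT3G48000	Oxydoreduction	1.7102
Q8RWN9	AT3G13930	Glycolysis	1.7859
Q96536		Glycolysis	2.1072
Q9LZR9	AT5G03690	Glycolysis	2.4066
Q9SJQ9	AT2G36460	Glycolysis	2.0721
O80725	AT2G47000	Transport	2.5087
Q8LE12		Transport	1.8569
Q94EG9	AT1G55910	Transport	1.7651
Q96303	AT2G38940	Transport	2.6498
Q9SAF5	AT1G13210	Transport	1.7937
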