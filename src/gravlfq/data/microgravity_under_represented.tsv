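uniprot	agi_locus	functional_category	ratio
P93025	AT5G58140	Signalling	0.51024
Q39192	AT3G50500	Signalling	0.55803
Q39253	AT2G38170	Signalling	0.36764
Q96262	AT4G20260	Signalling	0.73542
O04309	AT3G16470	Miscellaneous	0.62001
P15459	AT4G27160	Miscellaneous	0.47098
P38666	AT3G53020	Miscellaneous	0.42956
Q42586	AT3G54470	Miscellaneous	0.53952
Q8L7S8	AT5G26742	Miscellaneous	0.55758
Q9C5M3	AT1G78970	Miscellaneous	0.57192
Q9CAU9	AT3G04830	Miscellaneous	0.51415
Q9FZ47	AT1G16880	Miscellaneous	0.5611
Q9LKA6	AT3G14990	Miscellaneous	0.51174
Q9LTB2	AT5G49810	Miscellaneous	0.53697
Q9LUJ7	AT3G22640	Miscellaneous	0.53207
Q9SUR3	AT4G23630	Miscellaneous	0.45225
Q9T076	AT4G27520	Miscellaneous	0.41046
F4HYI6	AT1G48600	Lipid metabolism	0.56281
O04983	AT5G35360	Lipid metabolism	0.52901
Q9LD43	AT2G38040	Lipid metabolism	0.33612
P10798	AT5G38410	Chloroplast	0.35817
Q944I4	AT1G80380	Chloroplast	0.3499
Q41932	AT4G05180	Chloroplast	0.51641
Q9LEW2		Proteases	0.36835
Q9XEC4	AT4G04460	Proteases	0.4244
Q8L9T0		Unknown	0.52193
Q94EI1		Unknown	0.52207
Q9LYE7	AT5G11420	Unknown	0.36003
Q9SIL0		Unknown	0.5859
Q9SLV3	AT1G58270	Unknown	0.53874
Q9STW1	AT4G24330	Unknown	0.35208
Q9XI93	AT1G13930	Unknown	0.53415
O49313	AT2G33220	Respiratory chain	0.50406
P56774	ATCG00730	Respiratory chain	0.39674
O23629	AT3G45980	Nucleosome	0.36438
P26568	AT1G06760	Nucleosome	0.46852
Q94F49	AT5G27670	Nucleosome	0.21652
Q9FJE8	AT5G59870	Nucleosome	0.23441
Q9LQQ4	AT1G07790	Nucleosome	0.34323
Q9FM65	AT5G55730	Cell wall metabolism	0.3768
O22126	AT2G45470	Cell wall metabolism	0.87579
Q39099	AT2G06850	Cell wall metabolism	0.53895
Q9LIS3	AT3G23820	Cell wall metabolism	0.45798
Q9SG80	AT3G10740	Cell wall metabolism	0.58384
O65581	AT4G26530	Glycolysis	0.56419
Q9LF93		Glycolysis	0.1573
A1L4Y1	AT3G10350	Transport	0.5503
A8MR14	AT1G64650	Transport	0.56728
O23482	AT4G16370	Transport	0.29141
P26587	AT1G73190	Transport	0.48634
Q8L856	At4G25570	Transport	0.53011
Q9LJX0	AT3G28860	Transport	0.29547
Q9M817	AT1G52190	Transport	0.39512
Q9SMV6	AT5G17020	Transport	0.35214
B9DGT7	At1G50010	Cytoskeleton	0.6263
P29513	AT1G20010	Cytoskeleton	0.47936
P53492	AT5G09810	Cytoskeleton	0.6687
Q0WV25	At1G04820	Cytoskeleton	0.6263
Q56YW9	At5G62690	Cytoskeleton	0.43921
Q96292	AT3G18780	Cytoskeleton	0.53391
Q9ASR0	At5G62700	Cytoskeleton	0.43921
Q8LCQ9		Oxidoreductases	0.41902
Q94B78	AT4G33010	Oxidoreductases	0.44161
Q9SAE3	AT1G13090	Oxidoreductases	0.47906
Q9SGS4	AT1G76080	Oxidoreductases	0.55624
O23140	AT5G46630	Membrane trafficking	0.59061
O80977	AT2G14740	Membrane trafficking	0.55033
Q56WK6	AT1G72150	Membrane trafficking	0.58578
Q9XFM6	AT5G52240	Membrane trafficking	0.55566
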