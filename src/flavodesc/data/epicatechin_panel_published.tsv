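descriptor	EPI	E3'G	E3'S	3'ME5S	3'ME7S	gVL3'G	gVL3'S
homo	-137.081	-137.625	-140.496	-136.123	-134.664	-141.277	-161.897
lumo	-17.724	-17.623	-26.105	-20.535	-18.091	-16.502	-29.681
gap	119.357	120.001	114.391	115.587	116.573	124.775	132.216
ionization_potential	137.081	137.625	140.496	136.123	134.664	141.277	161.897
electron_affinity	17.724	17.623	26.105	20.535	18.091	16.502	29.681
chemical_potential	-77.403	-77.624	-83.301	-78.329	-76.377	-78.889	-95.789
hardness	59.678	60.001	57.195	57.794	58.286	62.387	66.108
softness_table	3298.988	3281.268	3442.212	3406.573	3377.768	3155.741	2978.126
electronegativity	77.403	77.624	83.301	78.329	76.377	78.889	95.789
electrophilicity	50.196	50.212	60.661	53.080	50.042	49.878	69.398
omega_plus	18.954	18.900	26.160	21.140	19.139	18.232	29.767
omega_minus	96.357	96.524	109.460	21.140	95.516	97.121	125.556
net_electrophilicity	115.311	115.424	135.620	120.609	114.655	115.353	155.323
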