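molecule_id	eps_homo	eps_lumo	unit
EPI	-137.081	-17.724	kcal_per_mol
E3'G	-137.625	-17.623	kcal_per_mol
E3'S	-140.496	-26.105	kcal_per_mol
3'ME5S	-136.123	-20.535	kcal_per_mol
3'ME7S	-134.664	-18.091	kcal_per_mol
gVL3'G	-141.277	-16.502	kcal_per_mol
gVL3'S	-161.897	-29.681	kcal_per_mol
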