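ChemicalEntity	NamedThing
BiologicalEntity	NamedThing
GeneOrProtein	BiologicalEntity
Gene	GeneOrProtein
Protein	GeneOrProtein
BiologicalProcessOrActivity	BiologicalEntity
BiologicalProcess	BiologicalProcessOrActivity
MolecularActivity	BiologicalProcessOrActivity
DiseaseOrPhenotypicFeature	BiologicalEntity
Disease	DiseaseOrPhenotypicFeature
PhenotypicFeature	DiseaseOrPhenotypicFeature
Cell	BiologicalEntity
AnatomicalEntity	BiologicalEntity
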