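new_name	short_name	sources
Caudate	caud	Caudate; Accumbens
Operculum	operc	Frontal Operculum Cortex; Central Opercular Cortex; Parietal Operculum Cortex
Calcarine Cortex	calc	Intracalcarine Cortex; Supracalcarine Cortex
Lentiform	lent	Putamen; Pallidum
Superior Temporal Gyrus	stg	Superior Temporal Gyrus posterior division; Superior Temporal Gyrus anterior division; Heschl's Gyrus (includes H1 and H2)
Inferior Temporal Gyrus	itg	Inferior Temporal Gyrus posterior division; Inferior Temporal Gyrus anterior division
Parahippocampal Gyrus	parhipc	Parahippocampal Gyrus posterior division; Parahippocampal Gyrus anterior division
Planum	plan	Planum Temporale; Planum Polare
Temporal Fusiform Cortex	tfus	Temporal Fusiform Cortex anterior division; Temporal Fusiform Cortex posterior division
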