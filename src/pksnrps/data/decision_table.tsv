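np_clade	level1_clade	status	kn_required	ter_required	required_mes	forbidden_mes	scaffold	representative_np
Ia-A	Ia	known	absent	absent	FMO,P450_Ia		tetramic_acid	pyranonigrin
Ia-B	Ia	known	absent	absent	reductase		tetramic_acid	xyrrolin
Ia-C	Ia	known	absent	absent	PT		tetramic_acid	cyclopiazonic acid
Ia-D-1	Ia	known	absent	present	expandase_P450	DAase	2-pyridone	tenellin
Ia-D-2	Ia	known	absent	present	expandase_P450,DAase:Iα		2-pyridone	leporin
Ia-D-3	Ia	known	absent	either	expandase_P450,DAase:Iβ		2-pyridone	illicicolin
Ib-A	Ib	known	absent	present	P450_Ib		tetramic_acid	burnettramic acid A
Ib-B	Ib	known	absent	either	aldolase,transaminase		tetramic_acid	Sch210972
Ib-C	Ib	known	absent	present	DAase:IIα		tetramic_acid	equisetin
Ib-D	Ib	known	absent	absent			tetramic_acid	fusaridione
II-A	II	known	present	absent	MT,P450_IIA		pyrrolinone	fusarin
II-B	II	known	present	present	P450_IIB		pyrrolinone	himeic acid
II-C	II	known	present	present	monooxygenase		pyrrolinone	flavipucine
II-D	II	known	present	absent	P450_IID		pyrrolinone	pseurotin
III-A	III	known	present	present	DAase:IIβ		pyrrolinone	chaetoglobosin
III-B	III	known	absent	present	P450_III,alphaKG		tetronic_acid	acyltetronic acid
III-C	III	known	present	present	DAase:IIβ,transaminase		pyrrolinone	oxaleimide
III-D	III	known	present	present	DAase:IIβ		pyrrolinone	cytochalasin
Ia-α	Ia	predicted
Ia-β	Ia	predicted
Ia-γ	Ia	predicted
Ia-δ	Ia	predicted		present	tER
Ia-ε	Ia	predicted
Ib-α	Ib	predicted
Ib-β	Ib	predicted
Ib-γ	Ib	predicted
II-α	II	predicted
II-β	II	predicted
II-γ	II	predicted
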