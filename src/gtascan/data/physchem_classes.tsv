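# 19 overlapping physicochemical amino-acid classes used by the class-composition
# encoder. This is an in-house table assembled from standard groupings (size,
# polarity, charge, chemistry, secondary-structure propensity, flexibility);
# it is editable but must contain exactly 19 non-empty classes.
class	residues
tiny	ACGST
small	ACDGNPSTV
aliphatic	ILV
aromatic	FHWY
hydrophobic	ACFGILMPVWY
polar	DEHKNQRSTY
charged	DEHKR
basic	HKR
acidic	DE
amide	NQ
hydroxyl	STY
sulfur	CM
imino	P
branched_chain	ILTV
helix_preferring	ACEHKLMQ
strand_preferring	FITVWY
turn_preferring	DGNPS
bulky	FIKLMRWY
flexible	DGKNPQS
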