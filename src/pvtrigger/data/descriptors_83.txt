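# Pinned 2D descriptor panel (83 named RDKit descriptors, fixed order)
MolWt
ExactMolWt
HeavyAtomMolWt
MolLogP
MolMR
NumHDonors
NumHAcceptors
NumHeteroatoms
NumRotatableBonds
TPSA
LabuteASA
Kappa1
Kappa2
Kappa3
Chi0
Chi1
Chi0n
Chi1n
Chi2n
Chi3n
Chi4n
Chi0v
Chi1v
Chi2v
Chi3v
Chi4v
HallKierAlpha
BertzCT
BalabanJ
Ipc
RingCount
NumAromaticRings
NumSaturatedRings
NumAliphaticRings
NumAromaticHeterocycles
NumAromaticCarbocycles
NumSaturatedHeterocycles
NumSaturatedCarbocycles
NumAliphaticHeterocycles
NumAliphaticCarbocycles
FractionCSP3
HeavyAtomCount
NHOHCount
NOCount
NumValenceElectrons
NumRadicalElectrons
MaxEStateIndex
MinEStateIndex
MaxAbsEStateIndex
MinAbsEStateIndex
MaxPartialCharge
MinPartialCharge
MaxAbsPartialCharge
MinAbsPartialCharge
EState_VSA1
EState_VSA2
EState_VSA3
EState_VSA4
EState_VSA5
EState_VSA6
EState_VSA7
EState_VSA8
EState_VSA9
EState_VSA10
VSA_EState1
VSA_EState2
VSA_EState3
VSA_EState4
VSA_EState5
VSA_EState6
VSA_EState7
VSA_EState8
VSA_EState9
VSA_EState10
SlogP_VSA1
SlogP_VSA2
SlogP_VSA3
SlogP_VSA4
SlogP_VSA5
SMR_VSA1
SMR_VSA2
SMR_VSA3
qed
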