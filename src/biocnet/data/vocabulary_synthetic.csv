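code,label,class,tier,description
BIO,bioculturalism,value,secondary,
CAB,commercial and business,value,secondary,
CEC,customary economy,value,secondary,
COM,commitment and caring for the environment,value,secondary,
CON,western conservation,value,secondary,
COT,recreation activities,value,secondary,
CUL,cultural expression,value,secondary,
GOV,governance,value,secondary,
HAR,harvesting,value,secondary,
HIS,ancestral activities,value,secondary,
ILK,indigenous and local knowledge,value,secondary,
MEN,mental health,value,secondary,
NOR,normalization of human-environment relationship,value,secondary,
OPE,operationalization,value,secondary,
PHY,physical health,value,secondary,
PRE,prestige,value,secondary,
PTA,people to ancestors,value,secondary,
PTL,people to location,value,secondary,
PTP,people to people,value,secondary,
SPI,spiritual health,value,secondary,
STE,stewardship,value,secondary,
TEA,teaching and learning processes,value,secondary,
SEA,sea,biophysical,,
LAND,land,biophysical,,
LAND_BIRDS,land birds,biophysical,,
SEABIRDS,seabirds,biophysical,,
PETRELS,grey-faced petrels,biophysical,,
TUATARA,tuatara,biophysical,,
GARDENS,gardens,biophysical,,
FISH,fish,biophysical,,
SHELLFISH,shellfish,biophysical,,
ROCKS,rocks,biophysical,,
REEFS,reefs,biophysical,,
BEACHES,beaches,biophysical,,
DUNES,sand dunes,biophysical,,
CLIFFS,cliffs,biophysical,,
CAVES,caves,biophysical,,
FRESHWATER,fresh water,biophysical,,
STREAMS,streams,biophysical,,
SPRINGS,springs,biophysical,,
RAIN,rain,biophysical,,
WIND,wind,biophysical,,
STARS,stars,biophysical,,
MOON,moon,biophysical,,
TIDES,tides,biophysical,,
CURRENTS,currents,biophysical,,
WAVES,waves,biophysical,,
HARBOURS,harbours,biophysical,,
HEADLANDS,headlands,biophysical,,
FOREST,coastal forest,biophysical,,
TREES,trees,biophysical,,
POHUTUKAWA,pohutukawa,biophysical,,
FLAX,flax,biophysical,,
FERNS,ferns,biophysical,,
KUMARA,kumara,biophysical,,
BERRIES,berries,biophysical,,
EELS,eels,biophysical,,
CRAYFISH,crayfish,biophysical,,
KINA,kina,biophysical,,
WHALES,whales,biophysical,,
DOLPHINS,dolphins,biophysical,,
SHARKS,sharks,biophysical,,
SEALS,seals,biophysical,,
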