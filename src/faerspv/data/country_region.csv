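country,region
AT,Europe
BA,Europe
BE,Europe
BG,Europe
BY,Europe
CH,Europe
CY,Europe
CZ,Europe
DE,Europe
DK,Europe
EE,Europe
ES,Europe
FI,Europe
FR,Europe
GB,Europe
GR,Europe
HR,Europe
HU,Europe
IE,Europe
IS,Europe
IT,Europe
LT,Europe
LU,Europe
LV,Europe
MD,Europe
MT,Europe
NL,Europe
NO,Europe
PL,Europe
PT,Europe
RO,Europe
RS,Europe
RU,Europe
SE,Europe
SI,Europe
SK,Europe
UA,Europe
AE,Asia
BD,Asia
CN,Asia
HK,Asia
ID,Asia
IL,Asia
IN,Asia
IQ,Asia
IR,Asia
JO,Asia
JP,Asia
KR,Asia
KW,Asia
KZ,Asia
LB,Asia
LK,Asia
MM,Asia
MY,Asia
PH,Asia
PK,Asia
QA,Asia
SA,Asia
SG,Asia
TH,Asia
TR,Asia
TW,Asia
UZ,Asia
VN,Asia
BM,North America
CA,North America
GL,North America
PM,North America
US,North America
AU,Oceania
FJ,Oceania
NC,Oceania
NZ,Oceania
PG,Oceania
AR,South and Central America
BB,South and Central America
BO,South and Central America
BR,South and Central America
BS,South and Central America
CL,South and Central America
CO,South and Central America
CR,South and Central America
CU,South and Central America
DO,South and Central America
EC,South and Central America
GT,South and Central America
HN,South and Central America
JM,South and Central America
MX,South and Central America
NI,South and Central America
PA,South and Central America
PE,South and Central America
PR,South and Central America
PY,South and Central America
SV,South and Central America
TT,South and Central America
UY,South and Central America
VE,South and Central America
AO,Africa
CD,Africa
CI,Africa
CM,Africa
DZ,Africa
EG,Africa
ET,Africa
GH,Africa
KE,Africa
LY,Africa
MA,Africa
MZ,Africa
NA,Africa
NG,Africa
SN,Africa
TN,Africa
TZ,Africa
UG,Africa
ZA,Africa
ZM,Africa
ZW,Africa
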