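iso3,continent
AGO,Africa
ARE,Asia
ARG,South America
AUS,Oceania
BGD,Asia
BRA,South America
CAN,North America
CHL,South America
CHN,Asia
COL,South America
CUB,North America
DEU,Europe
DNK,Europe
DOM,North America
ECU,South America
EGY,Africa
ESP,Europe
EST,Europe
FIN,Europe
FJI,Oceania
FRA,Europe
FRO,Europe
FSM,Oceania
GBR,Europe
GHA,Africa
GRC,Europe
GTM,North America
GUY,South America
HND,North America
HRV,Europe
IDN,Asia
IND,Asia
IRL,Europe
IRN,Asia
ISL,Europe
ISR,Asia
ITA,Europe
JAM,North America
JPN,Asia
KHM,Asia
KIR,Oceania
KOR,Asia
LKA,Asia
LTU,Europe
LVA,Europe
MAR,Africa
MDG,Africa
MEX,North America
MHL,Oceania
MMR,Asia
MOZ,Africa
MRT,Africa
MYS,Asia
NAM,Africa
NGA,Africa
NIC,North America
NLD,Europe
NOR,Europe
NZL,Oceania
OMN,Asia
PAK,Asia
PAN,North America
PER,South America
PHL,Asia
PNG,Oceania
POL,Europe
PRT,Europe
RUS,Europe
SAU,Asia
SEN,Africa
SLB,Oceania
SUR,South America
SWE,Europe
SYC,Africa
THA,Asia
TON,Oceania
TUN,Africa
TUR,Asia
TWN,Asia
TZA,Africa
URY,South America
USA,North America
VEN,South America
VNM,Asia
VUT,Oceania
WSM,Oceania
YEM,Asia
ZAF,Africa
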