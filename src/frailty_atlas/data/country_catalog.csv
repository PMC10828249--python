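# Default 42-country catalog: 29 countries with survey data + 13 prediction-only.
# GDP per capita (mean 2000-2004, thousand EUR; market prices and PPP-adjusted)
# are approximate public figures for demonstration/synthetic runs; supply a
# prepared country-attributes file for real analyses.
country,name,share_participant,gdp_kEUR,gdp_kEUR_ppp
AT,Austria,True,27.5,27.0
BE,Belgium,True,26.0,26.5
BG,Bulgaria,True,2.1,6.7
HR,Croatia,True,5.6,10.5
CY,Cyprus,True,15.5,18.5
CZ,Czechia,True,8.1,15.9
DK,Denmark,True,35.0,27.5
EE,Estonia,True,5.8,10.5
FI,Finland,True,27.5,25.0
FR,France,True,25.0,25.0
DE,Germany,True,26.0,24.5
GR,Greece,True,14.0,18.0
HU,Hungary,True,6.9,13.0
IE,Ireland,True,31.0,29.5
IL,Israel,True,18.5,19.5
IT,Italy,True,22.5,23.5
LV,Latvia,True,4.3,8.8
LT,Lithuania,True,4.6,9.5
LU,Luxembourg,True,53.0,50.0
MT,Malta,True,10.5,16.5
NL,Netherlands,True,28.5,28.0
PL,Poland,True,5.2,10.3
PT,Portugal,True,13.0,16.5
RO,Romania,True,2.2,6.3
SK,Slovakia,True,5.3,11.0
SI,Slovenia,True,12.5,17.5
ES,Spain,True,17.5,20.5
SE,Sweden,True,30.0,26.0
CH,Switzerland,True,37.5,30.0
AL,Albania,False,1.5,4.3
BY,Belarus,False,1.5,6.0
BA,Bosnia and Herzegovina,False,1.7,5.3
IS,Iceland,False,30.5,26.5
XK,Kosovo,False,1.3,3.9
MD,Moldova,False,0.5,2.2
ME,Montenegro,False,2.0,6.0
MK,North Macedonia,False,2.0,5.9
NO,Norway,False,40.0,32.0
RU,Russia,False,2.5,7.7
RS,Serbia,False,2.1,6.4
UA,Ukraine,False,0.9,4.6
GB,United Kingdom,False,28.5,25.5
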