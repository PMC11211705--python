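surface_form,iso2
Afghanistan,AF
Afghan,AF
Albania,AL
Algeria,DZ
Andorra,AD
Angola,AO
Argentina,AR
Argentine,AR
Armenia,AM
Australia,AU
Australian,AU
Austria,AT
Austrian,AT
Azerbaijan,AZ
Bahamas,BS
Bahrain,BH
Bangladesh,BD
Bangladeshi,BD
Barbados,BB
Belarus,BY
Belgium,BE
Belgian,BE
Belize,BZ
Benin,BJ
Bhutan,BT
Bolivia,BO
Bosnia and Herzegovina,BA
Botswana,BW
Brazil,BR
Brazilian,BR
Brunei,BN
Bulgaria,BG
Bulgarian,BG
Burkina Faso,BF
Burundi,BI
Cambodia,KH
Cambodian,KH
Cameroon,CM
Canada,CA
Canadian,CA
Cape Verde,CV
Central African Republic,CF
Chad,TD
Chile,CL
Chilean,CL
China,CN
Chinese,CN
Colombia,CO
Colombian,CO
Comoros,KM
Costa Rica,CR
Croatia,HR
Croatian,HR
Cuba,CU
Cuban,CU
Cyprus,CY
Czech Republic,CZ
Czechia,CZ
Democratic Republic of the Congo,CD
DR Congo,CD
Republic of the Congo,CG
Denmark,DK
Danish,DK
Djibouti,DJ
Dominica,DM
Dominican Republic,DO
Ecuador,EC
Egypt,EG
Egyptian,EG
El Salvador,SV
Equatorial Guinea,GQ
Eritrea,ER
Estonia,EE
Eswatini,SZ
Ethiopia,ET
Ethiopian,ET
Fiji,FJ
Finland,FI
Finnish,FI
France,FR
French,FR
Gabon,GA
Gambia,GM
Georgia,GE
Germany,DE
German,DE
Ghana,GH
Ghanaian,GH
Greece,GR
Greek,GR
Grenada,GD
Guatemala,GT
Guinea,GN
Guinea-Bissau,GW
Guyana,GY
Haiti,HT
Haitian,HT
Honduras,HN
Hungary,HU
Hungarian,HU
Iceland,IS
India,IN
Indian,IN
Indonesia,ID
Indonesian,ID
Iran,IR
Iranian,IR
Iraq,IQ
Iraqi,IQ
Ireland,IE
Irish,IE
Israel,IL
Israeli,IL
Italy,IT
Italian,IT
Ivory Coast,CI
Cote d'Ivoire,CI
Jamaica,JM
Jamaican,JM
Japan,JP
Japanese,JP
Jordan,JO
Kazakhstan,KZ
Kenya,KE
Kenyan,KE
Kiribati,KI
Kuwait,KW
Kyrgyzstan,KG
Laos,LA
Latvia,LV
Lebanon,LB
Lebanese,LB
Lesotho,LS
Liberia,LR
Libya,LY
Liechtenstein,LI
Lithuania,LT
Luxembourg,LU
Madagascar,MG
Malawi,MW
Malaysia,MY
Malaysian,MY
Maldives,MV
Mali,ML
Malta,MT
Marshall Islands,MH
Mauritania,MR
Mauritius,MU
Mexico,MX
Mexican,MX
Micronesia,FM
Moldova,MD
Monaco,MC
Mongolia,MN
Montenegro,ME
Morocco,MA
Moroccan,MA
Mozambique,MZ
Myanmar,MM
Namibia,NA
Nauru,NR
Nepal,NP
Nepali,NP
Netherlands,NL
Dutch,NL
New Zealand,NZ
Nicaragua,NI
Niger,NE
Nigeria,NG
Nigerian,NG
North Korea,KP
North Macedonia,MK
Norway,NO
Norwegian,NO
Oman,OM
Pakistan,PK
Pakistani,PK
Palau,PW
Panama,PA
Papua New Guinea,PG
Paraguay,PY
Peru,PE
Peruvian,PE
Philippines,PH
Filipino,PH
Poland,PL
Polish,PL
Portugal,PT
Portuguese,PT
Qatar,QA
Romania,RO
Romanian,RO
Russia,RU
Russian,RU
Rwanda,RW
Rwandan,RW
Saint Lucia,LC
Samoa,WS
San Marino,SM
Saudi Arabia,SA
Saudi,SA
Senegal,SN
Senegalese,SN
Serbia,RS
Serbian,RS
Seychelles,SC
Sierra Leone,SL
Singapore,SG
Singaporean,SG
Slovakia,SK
Slovenia,SI
Solomon Islands,SB
Somalia,SO
Somali,SO
South Africa,ZA
South African,ZA
South Korea,KR
South Sudan,SS
Spain,ES
Spanish,ES
Sri Lanka,LK
Sudan,SD
Sudanese,SD
Suriname,SR
Sweden,SE
Swedish,SE
Switzerland,CH
Swiss,CH
Syria,SY
Syrian,SY
Taiwan,TW
Taiwanese,TW
Tajikistan,TJ
Tanzania,TZ
Tanzanian,TZ
Thailand,TH
Thai,TH
Timor-Leste,TL
Togo,TG
Tonga,TO
Trinidad and Tobago,TT
Tunisia,TN
Tunisian,TN
Turkey,TR
Turkish,TR
Turkmenistan,TM
Tuvalu,TV
Uganda,UG
Ugandan,UG
Ukraine,UA
Ukrainian,UA
United Arab Emirates,AE
UAE,AE
United Kingdom,GB
Britain,GB
British,GB
England,GB
Scotland,GB
Wales,GB
United States,US
United States of America,US
USA,US
Uruguay,UY
Uzbekistan,UZ
Vanuatu,VU
Venezuela,VE
Venezuelan,VE
Vietnam,VN
Vietnamese,VN
Yemen,YE
Yemeni,YE
Zambia,ZM
Zambian,ZM
Zimbabwe,ZW
Zimbabwean,ZW
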