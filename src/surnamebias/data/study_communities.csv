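community_id,region,province,oldest_kind,oldest_year,present_kind,present_year,n0,nt,s0,st,altitude_m,printed_growth_rate
Commezzadura,Trentino-Alto Adige,TN,marriage,1700,phonebook,1993,297,350,44,166,850,0.15
Pellizzano,Trentino-Alto Adige,TN,marriage,1700,phonebook,1993,548,324,85,134,925,-0.69
Rabbi,Trentino-Alto Adige,TN,marriage,1566,phonebook,1993,292,482,88,103,1095,0.39
Vermiglio,Trentino-Alto Adige,TN,marriage,1714,phonebook,1993,341,462,28,68,1261,0.26
Azeglio,Piedmont,TO,baptismal,1543,phonebook,1993,895,423,100,217,260,-1.12
Ivrea,Piedmont,TO,census,1613,phonebook,1993,3835,9816,568,4861,253,0.61
Moncalieri,Piedmont,TO,census,1613,phonebook,1993,6129,20436,776,9382,219,0.7
Susa,Piedmont,TO,census,1613,phonebook,1993,4447,2283,341,1276,503,-0.95
Levanto,Liguria,SP,census,1662,phonebook,1993,1728,5716,329,1151,3,0.7
Nonantola,Emilia-Romagna,MO,census,1629,phonebook,1993,3451,3407,181,1092,24,-0.01
Careggine,Tuscany,LU,marriage,1566,phonebook,1993,243,206,115,70,882,-0.18
Montecarlo,Tuscany,LU,baptismal,1527,phonebook,1993,3913,1226,283,545,162,-2.09
Montefegatesi,Tuscany,LU,marriage,1600,municipal,1991,398,270,108,55,842,-0.47
Pisa,Tuscany,PI,baptismal,1447,phonebook,1993,17504,35921,1830,10913,4,0.51
Roggio,Tuscany,LU,marriage,1775,municipal,1991,115,175,30,41,858,0.34
San Gimignano,Tuscany,SI,marriage,1700,phonebook,1993,290,2357,73,1013,324,0.88
Siena,Tuscany,SI,census,1767,phonebook,1993,2941,56956,1373,5626,322,0.95
Vagli,Tuscany,LU,marriage,1700,phonebook,1993,553,379,96,100,575,-0.46
Viareggio,Tuscany,LU,census,1705,phonebook,1993,290,57514,86,7263,2,0.99
Pontremoli,Tuscany,MS,marriage,1559,phonebook,1993,249,3400,61,976,236,0.93
Cerchio,Abruzzo,AQ,census,1700,phonebook,1993,932,1735,144,146,834,0.46
Bari,Puglia,BA,census,1598,phonebook,1993,8872,111221,1065,12993,5,0.92
Bagaladi,Calabria,RC,baptismal,1657,phonebook,1993,125,399,31,120,460,0.69
Cannavo,Calabria,RC,baptismal,1601,municipal,2001,994,3935,274,577,147,0.75
Cardeto,Calabria,RC,baptismal,1670,phonebook,1993,924,695,129,129,700,-0.33
Trizzino,Calabria,RC,baptismal,1706,municipal,2001,137,104,34,28,551,-0.32
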