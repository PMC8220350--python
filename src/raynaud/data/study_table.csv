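study,year,country,city,latitude,sample_size,mean_age,prevalence
Brand,1997,USA,Boston,42.36,4182,51.8,7.20
Fraenkel,1999,USA,Boston,42.36,1525,53.9,7.80
Harada,1991,Japan,Ehime,33.84,3873,20-70,1.60
Ivorra,2001,Spain,Valencia,39.47,276,54.4,3.30
Maricq,1997,USA,South Carolina,33.84,2518,>18,2.10
Maricq,1997,France,Toulon,43.12,2187,>18,7.10
Maricq,1997,France,Nyons,44.36,2341,>18,6.00
Maricq,1997,France,Grenoble,45.19,2341,>18,9.25
Maricq,1997,France,Tarentaise,45.37,2296,>18,11.05
Onbasi,2005,Turkey,Van,38.50,768,29.2,5.90
Heslop,1983,UK,Southampton,50.91,450,20-59,12.70
Purdie,2009,New Zealand,Wellington,41.25,234,>18,11.50
Sahin,2003,Turkey,Van,38.50,251,28.9,3.98
Leppert,1987,Sweden,Vasteras,59.61,2705,18-59,11.00
Olsen,1978,Denmark,Copenhagen,55.68,67,21-50,15.51
Tzilalis,2011,Greece,Athens,37.98,3912,18-28,0.31
Cakir,2008,Turkey,Edirne,41.15,1414,27.2,3.60
Gallo,1994,Italy,Milan,45.46,1920,15-84,4.20
Voulgari,2000,Greece,Ioannina,39.77,500,33.7,5.20
Jones,2003,UK,Manchester,53.48,716,12-15,14.90
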