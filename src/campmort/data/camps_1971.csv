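camp_name,state,population,deaths,start_date,end_date,cause_class,official_source,source_note
Salt Lake,West Bengal,170000,3671,1971-07-01,1971-11-30,general,false,camp survey; general deaths only
Salt Lake,West Bengal,170000,1250,1971-06-01,1971-06-08,monsoon_excess,true,cholera deaths only; official count
Itkhola,West Bengal,18000,17,1971-06-01,1971-06-12,general,false,general deaths only
Karimpur,West Bengal,15000,700,1971-06-01,1971-06-17,monsoon_excess,false,cholera deaths only
Boyra,West Bengal,40000,5000,1971-06-01,1971-08-01,monsoon_excess,false,cholera deaths only
Kalyani,West Bengal,50000,500,1971-06-01,1971-06-30,monsoon_excess,true,cholera deaths only; official count
Nadia district,West Bengal,250000,1000,1971-06-01,1971-06-05,monsoon_excess,true,cholera deaths only; official count
Barasat jail compound,West Bengal,3000,166,1971-03-25,1971-10-27,all,false,all deaths
Barasat hospital,West Bengal,7000,1250,1971-07-01,1971-07-25,all,false,all deaths
Banjetia and Lalbagh,West Bengal,20000,1000,1971-06-01,1971-12-16,all,true,all deaths; official count
Balat and Mailam,Meghalaya,171000,2000,1971-09-15,1971-09-30,monsoon_excess,false,cholera deaths only
My Long (Myilliem),Meghalaya,80000,3500,1971-05-01,1971-06-30,monsoon_excess,false,cholera and pneumonia deaths
Ampati,Meghalaya,45000,3500,1971-05-01,1971-12-16,all,false,all deaths
Chapor,Assam,50000,500,1971-05-01,1971-12-16,all,true,all deaths; official count
Jambu Island,Orissa,33000,5000,1971-10-29,1971-11-06,monsoon_excess,false,cyclone deaths only
Mana,Madhya Pradesh,137000,80,1971-06-21,1971-07-03,general,false,general deaths only
Mana,Madhya Pradesh,60000,819,1971-09-01,1971-09-21,monsoon_excess,false,cholera deaths only
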