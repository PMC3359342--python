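# Sampled stations: geography, MODIS-climatology environment and sample sizes.
# Coordinates are decimal degrees printed with degree/prime marks (D°MM′H reads
# as D.MM decimal degrees; minutes field may exceed 59); south/west negative.
# mean_temp_C: mean annual sea-surface temperature; mean_chla: mg m^-3.
station_id,name,latitude,longitude,mean_temp_C,mean_chla,n_vb,age_max_vb,n_dg,age_max_dg
1,Vigo,42°23′N,8°71′W,15.28,4.84,71,7,11,4
2,Ile de Re,46°20′N,1°40′W,15.18,3.98,51,6,15,3
3,Bay of Brest,48°23′N,4°28′W,13.23,3.14,60,6,32,4
4,Bay of Seine,49°50′N,0°19′W,13.00,7.37,52,6,29,3
5,Plymouth,50°20′N,4°08′W,13.49,2.34,30,6,18,4
6,Holyhead,53°03′N,4°42′W,11.37,2.98,34,9,14,4
7,Scarborough,54°19′N,0°06′E,10.51,4.03,51,7,17,5
8,Campbell Town,55°26′N,5°31′W,10.42,9.31,50,7,27,4
9,Austevoll,60°06′N,5°10′E,7.92,6.54,13,7,38,6
10,Bessaker,64°15′N,10°19′E,8.46,6.28,33,9,15,6
11,Bronnoysund,65°27′N,11°25′E,7.62,2.44,50,10,8,5
12,Traena,66°30′N,12°21′E,8.01,1.26,50,11,23,6
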