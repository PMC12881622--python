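region,region_area_ha,forest_ha,coniferous_ha,broadleaved_ha,period,woody_to_nonwoody_ha,burnt_ha
Lviv,2182326,807144,249946,557198,2020-2021,1964,51
Lviv,2182326,807144,249946,557198,2021-2022,4370,127
Kyiv,2894914,812360,450456,361904,2020-2021,2666,2415
Kyiv,2894914,812360,450456,361904,2021-2022,5659,5991
Zhytomyr,2983789,1212749,578562,634187,2020-2021,5806,1186
Zhytomyr,2983789,1212749,578562,634187,2021-2022,10622,1456
Kharkiv,3143488,431179,,,2020-2021,1518,655
Kharkiv,3143488,431179,,,2021-2022,2543,4632
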