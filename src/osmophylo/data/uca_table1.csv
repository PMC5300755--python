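species,region,habitat_mosm,habitat_se,hemolymph_mosm,hemolymph_se,ll50,ul50,ul50_se,osm_ll50,osm_ll50_se,osm_ul50,osm_ul50_se,isosmotic_point,isosmotic_se,rc_hyper,rc_hyper_se,rc_hypo,rc_hypo_se,reference
U_minax,Americas,70,,600,25,,2000,,570,,1590,,667,,0.86,,0.31,,Thurman 2002
U_mordax,Americas,150,38,558,9,,1453,54,492,9,1057,68,579,15,0.84,0.02,0.43,0.07,Present study
U_vocator,Americas,305,87,653,16,,2038,105,558,14,967,41,659,24,0.85,0.05,0.78,0.00,Present study
U_victoriana,Americas,338,82,677,27,,1825,151,602,26,1036,36,676,21,0.89,0.02,0.64,0.09,Present study
U_burgersi,Americas,349,79,670,17,,1924,63,608,11,1218,77,669,11,0.91,0.02,0.56,0.07,Present study
U_longisignalis,Americas,367,,685,15,,2230,,585,,1230,,693,,0.84,,0.65,,Thurman 2003a
U_cumulanta,Americas,385,107,702,24,151,1905,95,645,10,1006,45,752,26,0.84,0.03,0.79,0.02,Present study
U_spinicarpa,Americas,387,81,644,12,,2030,,600,,1130,,682,,0.88,,0.67,,Thurman 2003a
U_rapax,Americas,476,63,778,8,,2475,141,680,14,1195,49,762,12,0.89,0.02,0.74,0.03,Present study
U_uruguayensis,Americas,500,87,759,18,,2307,185,610,29,1360,51,748,19,0.82,0.02,0.6,0.04,Present study
U_thayeri,Americas,529,63,770,12,99,1783,49,673,15,1153,30,765,11,0.87,0.02,0.61,0.04,Present study
U_panacea,Americas,548,102,796,11,,2975,,660,,1440,,822,,0.75,,0.71,,Thurman 2003a
U_maracoani,Americas,606,72,835,15,153,1786,92,713,11,1277,44,912,10,0.75,0.01,0.57,0.04,Present study
U_leptodactyla,Americas,609,84,787,11,33,2585,61,620,17,1303,77,800,16,0.77,0.03,0.72,0.04,Present study
U_pugilator,Americas,694,185,850,33,,3270,,620,,1660,,816,,0.76,,0.66,,Thurman 2003a
U_pugnax,Americas,763,54,805,15,100,2700,,700,,1600,,879,,0.77,,0.6,,Thurman 2003b
U_subcylindrica,Americas,882,599,785,20,100,3200,,800,,1520,,845,,0.94,,0.71,,Thurman 2002
U_crenulata,Americas,917,,912,18,58,2910,,500,,1400,,888,,0.53,,0.75,,Thurman 2005
U_major,Americas,1129,,997,,91,2672,,750,,1400,,930,,0.79,,0.8,,Thurman 2010
U_speciosa,Americas,1149,,903,,,2958,,700,,1400,,822,,0.85,,0.81,,Thurman 2010
U_arcuata,Indo-west Pacific,339,81,715,,,1350,,590,,1230,,906,,0.65,,0.27,,Lin et al. 2002
U_lactea,Indo-west Pacific,1083,24,830,,15,1800,,500,,1700,,895,,0.55,,0.11,,Lin et al. 2002
U_vocans,Indo-west Pacific,1179,24,812,,15,1800,,450,,1750,,911,,0.49,,0.06,,Lin et al. 2002
U_formosensis,Indo-west Pacific,1257,33,875,,15,1800,,500,,1510,,1009,,0.49,,0.37,,Lin et al. 2002
U_inversa,Indo-west Pacific,1260,,1177,,171,1350,,763,,1226,,1080,,0.65,,0.46,,Spaargaren 1977
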