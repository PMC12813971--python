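glyco_site,conformer,probability,slot,site_class,pcs_ppm,rdc_hz
NG1,NG1-c1,0.5779438080664488,acetyl_1,acetyl,1.8414195424753412,7.089917581825883
NG1,NG1-c1,0.5779438080664488,acetyl_2,acetyl,0.9439877647359758,-0.2784591205525167
NG1,NG1-c1,0.5779438080664488,first_C1,first_C1,2.4862922255139055,-26.119437865482585
NG1,NG1-c1,0.5779438080664488,second_C1,second_C1,0.8978293868828885,-28.63595553522608
NG1,NG1-c2,0.24794213009464316,acetyl_1,acetyl,1.7011673960654818,-4.960288395964216
NG1,NG1-c2,0.24794213009464316,acetyl_2,acetyl,0.9251866072035739,3.9855251527479187
NG1,NG1-c2,0.24794213009464316,first_C1,first_C1,2.6232842679193515,-2.721659865812688
NG1,NG1-c2,0.24794213009464316,second_C1,second_C1,6.984972491488132,-24.244795747607707
NG1,NG1-c3,0.1630490577958428,acetyl_1,acetyl,1.6398175476885153,-5.555824347014329
NG1,NG1-c3,0.1630490577958428,acetyl_2,acetyl,0.9330962053925573,2.8874774680396453
NG1,NG1-c3,0.1630490577958428,first_C1,first_C1,1.8125433058481217,-21.411130828984025
NG1,NG1-c3,0.1630490577958428,second_C1,second_C1,1.6161241922638443,28.25189732534872
NG1,NG1-c4,0.011065004043065188,acetyl_1,acetyl,1.300044436501018,3.802253767635747
NG1,NG1-c4,0.011065004043065188,acetyl_2,acetyl,2.8343848634260866,4.084132664555414
NG1,NG1-c4,0.011065004043065188,first_C1,first_C1,2.119667540046818,-13.827883018508004
NG1,NG1-c4,0.011065004043065188,second_C1,second_C1,2.0937577292754566,28.337556705222557
NG2,NG2-c1,0.45466289115671676,acetyl_1,acetyl,0.46819743702866434,-12.523689103449115
NG2,NG2-c1,0.45466289115671676,acetyl_2,acetyl,0.989908125264442,-12.171870529474075
NG2,NG2-c1,0.45466289115671676,first_C1,first_C1,0.35392783232244807,11.039284190495339
NG2,NG2-c1,0.45466289115671676,second_C1,second_C1,0.6259803785012429,-8.346151619032387
NG2,NG2-c2,0.20744830064866338,acetyl_1,acetyl,1.698049355599556,4.556336226734972
NG2,NG2-c2,0.20744830064866338,acetyl_2,acetyl,0.5146866668263911,-8.292252225811831
NG2,NG2-c2,0.20744830064866338,first_C1,first_C1,1.0351684998939648,-19.0421561604961
NG2,NG2-c2,0.20744830064866338,second_C1,second_C1,0.6716177102413532,7.244777066985843
NG2,NG2-c3,0.17700548722634488,acetyl_1,acetyl,0.6464488957594732,8.977842398102167
NG2,NG2-c3,0.17700548722634488,acetyl_2,acetyl,0.4926413794169204,3.706660938226042
NG2,NG2-c3,0.17700548722634488,first_C1,first_C1,0.3819606220506883,-26.73886029509754
NG2,NG2-c3,0.17700548722634488,second_C1,second_C1,0.3835455274473412,31.63831278316229
NG2,NG2-c4,0.16088332096827487,acetyl_1,acetyl,0.5794723517806734,6.541769446792288
NG2,NG2-c4,0.16088332096827487,acetyl_2,acetyl,0.43024841454339113,1.3809980279945395
NG2,NG2-c4,0.16088332096827487,first_C1,first_C1,0.9491022184341572,15.535335237677318
NG2,NG2-c4,0.16088332096827487,second_C1,second_C1,0.5173954810331024,23.14185293833321
NG3,NG3-c1,0.402766192253548,acetyl_1,acetyl,0.190797181800978,-10.059761225271137
NG3,NG3-c1,0.402766192253548,acetyl_2,acetyl,0.29539217096170056,-4.359295430534937
NG3,NG3-c1,0.402766192253548,first_C1,first_C1,0.1385646911675075,-9.924836464443201
NG3,NG3-c1,0.402766192253548,second_C1,second_C1,0.24593726112312145,-14.285659912837936
NG3,NG3-c2,0.3113657581274649,acetyl_1,acetyl,0.19139911143881339,-0.5969314217035857
NG3,NG3-c2,0.3113657581274649,acetyl_2,acetyl,0.13392255017841087,2.96740892177855
NG3,NG3-c2,0.3113657581274649,first_C1,first_C1,0.19578426930428552,-22.523510884231182
NG3,NG3-c2,0.3113657581274649,second_C1,second_C1,0.11606075744659053,-25.362954073535178
NG3,NG3-c3,0.17859713265861482,acetyl_1,acetyl,0.05629984399253572,-8.987480783164672
NG3,NG3-c3,0.17859713265861482,acetyl_2,acetyl,0.06703023566678126,2.965033630289868
NG3,NG3-c3,0.17859713265861482,first_C1,first_C1,0.09244730499986879,0.3871030117999714
NG3,NG3-c3,0.17859713265861482,second_C1,second_C1,0.10751354949528072,-14.30489466853569
NG3,NG3-c4,0.10727091696037233,acetyl_1,acetyl,0.12469041800044414,-2.073976013946912
NG3,NG3-c4,0.10727091696037233,acetyl_2,acetyl,0.0724375059105461,-6.232440335383754
NG3,NG3-c4,0.10727091696037233,first_C1,first_C1,0.11427925891494278,-12.21885693255368
NG3,NG3-c4,0.10727091696037233,second_C1,second_C1,0.08590441365712054,-27.350416754763867
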