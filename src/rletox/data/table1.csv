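species,toxicant,intercept_b_ugL,slope_a,r_squared,reported_nlt_days,printed_calculated_ln_nlt,flag,source_ref
Oreochromis niloticus,Dimethoate,36000,-7800,0.949,500,6.18,,"Phommakone 2004"
Oreochromis niloticus,Dimethoate,34000,-3400,0.900,500,6.18,,"Phommakone 2004"
Oreochromis niloticus,Captan,580,-130,0.984,500,6.18,,"Boran et al. 2012"
Oreochromis niloticus,"2,3,4,5-Tetrachlorophenol",310,-58,0.627,500,6.18,,"Holcombe et al. 1984"
Oncorhynchus gorbuscha,Glyphosate,130000,-50000,0.962,600,4.78,,"Wan et al. 1989"
Oncorhynchus gorbuscha,MOW0818,3300,-640,0.985,600,4.78,,"Wan et al. 1989"
Oncorhynchus gorbuscha,MOW8709,60000,-21000,0.943,600,4.78,,"Wan et al. 1989"
Oncorhynchus gorbuscha,Roundup,28000,-3000,0.957,600,4.78,,"Wan et al. 1989"
Salmo gairdneri,"2,3,4,5-Tetrachlorophenol",100000,-9400,0.832,3300,8.6,,"Holcombe et al. 1984"
Salmo gairdneri,Glyphosate,2600,-360,0.977,3300,8.6,,"Wan et al. 1989"
Salmo gairdneri,MW0818,45000,-10000,0.986,3300,8.6,,"Wan et al. 1989"
Salmo gairdneri,MOW8709,22000,-1800,0.982,3300,8.6,,"Wan et al. 1989"
Oncorhynchus tshawytesha,Glyphosate,110000,-17000,0.885,2100,7.60,,"Wan et al. 1989"
Oncorhynchus tshawytesha,MW0818,3000,-360,0.905,2100,7.60,,"Wan et al. 1989"
Oncorhynchus tshawytesha,MOW8709,58000,-7900,0.984,2100,7.60,,"Wan et al. 1989"
Oncorhynchus tshawytesha,Roundup,29000,-3600,0.978,2100,7.60,,"Wan et al. 1989"
Oncorhynchus keta,Glyphosate,89000,-14000,0.998,2700,8.23,,"Wan et al. 1989"
Oncorhynchus keta,MOW0818,2400,-190,0.818,2700,8.23,,"Wan et al. 1989"
Oncorhynchus keta,MOW8709,44000,-4900,0.956,2700,8.23,,"Wan et al. 1989"
Oncorhynchus keta,Roundup,23000,-4400,0.980,2700,8.23,,"Wan et al. 1989"
Oncorhynchus kisutch,Glyphosate,12000,-2000,0.984,1800,7.88,,"Wan et al. 1989"
Oncorhynchus kisutch,MOW0818,3300,-310,0.820,1800,7.88,,"Wan et al. 1989"
Oncorhynchus kisutch,MOW8709,48000,-5200,0.823,1800,7.88,,"Wan et al. 1989"
Oncorhynchus kisutch,Roundup,34000,-5100,0.972,1800,7.88,,"Wan et al. 1989"
Anguilla anguilla,Methylparathion,5400,-870,0.977,4700,8.22,ambiguous_intercept,"Ferrando et al. 1991"
Anguilla anguilla,Methildathion,3700,-1700,0.967,4700,8.22,,"Ferrando et al. 1991"
Anguilla anguilla,Chlorpyrifos,1200,-550,0.905,4700,8.22,,"Ferrando et al. 1991"
Anguilla anguilla,Trichlorfon,4900,-1200,0.930,4700,8.22,,"Ferrando et al. 1991"
Anguilla anguilla,Fenitrothion,340,-130,0.817,4700,8.22,,"Ferrando et al. 1991"
Anguilla anguilla,Endosulfan,52,-1.3,0.742,4700,8.22,,"Ferrando et al. 1991"
Anguilla anguilla,Diazinon,160,-59,0.981,4700,8.22,,"Ferrando et al. 1991"
Heteropneustes fossilis,Dimethoate,17000,-1600,0.930,6600,9.02,,""
Heteropneustes fossilis,Dimethoate,3400,-300,0.966,6600,9.02,,"Pandey et al. 2009"
Heteropneustes fossilis,Dimethoate,3400,-290,0.982,6600,9.02,,"Pandey et al. 2009"
Heteropneustes fossilis,Chlordane,500,-86,0.992,6600,9.02,,"Pandey et al. 2008"
Heteropneustes fossilis,Ekatin,13000,-1100,0.929,6600,9.02,,"Verma et al. 1978"
Heteropneustes fossilis,Ekalaux,2800,-900,0.943,6600,9.02,,"Verma et al. 1978"
Heteropneustes fossilis,Sumithion,15000,-1600,0.871,6600,9.02,,"Verma et al. 1978"
Poecilia reticulata,Benzonitrile,59000,-12000,0.931,550,5.4,,"Verhaar et al. 1999"
Poecilia reticulata,Benzaldehyde,240000,-42000,0.908,550,5.4,,"Verhaar et al. 1999"
Poecilia reticulata,Benzylalcohol,23000,-6200,0.830,550,5.4,,"Verhaar et al. 1999"
Poecilia reticulata,Cypermethrin,640000,-210000,0.911,550,5.4,,"Verhaar et al. 1999"
Poecilia reticulata,Cypermethrin,3200,-670,0.978,550,5.4,,"Gautara and Gupta 2008"
Poecilia reticulata,Cypermethrin,2200,-360,0.956,550,5.4,,"Gautara and Gupta 2008"
Poecilia reticulata,Cypermethrin,1900,-280,0.991,550,5.4,,"Gautara and Gupta 2008"
Poecilia reticulata,Cypermethrin,1800,-210,0.962,550,5.4,,"Gautara and Gupta 2008"
Poecilia reticulata,Cypermethrin,2500,-520,0.978,550,5.4,,"Gautara and Gupta 2008"
Poecilia reticulata,Cypermethrin,2400,-460,0.983,550,5.4,,"Gautara and Gupta 2008"
Pimephales promelas,2-Allylphenol,32000,-15000,0.915,720,6.59,,"Holcombe et al. 1984"
Pimephales promelas,4-Tert-butylphenol,6200,-800,0.989,720,6.59,,"Holcombe et al. 1984"
Pimephales promelas,4-Chloro-3-methylphenol,14000,-4100,0.966,720,6.59,,"Holcombe et al. 1984"
Pimephales promelas,4-Nitrophenol,65000,-18000,0.985,720,6.59,,"Holcombe et al. 1984"
Pimephales promelas,"2,3,4,5-Tetraphenyl",490,-40,0.882,720,6.59,,"Holcombe et al. 1984"
Pimephales promelas,"1,4-Dinitrobenzene",690,-60,0.982,720,6.59,,"Holcombe et al. 1984"
Ictalurus punctatus,"1,4-Dinitrobenzene",910,-170,0.971,2900,,,"Holcombe et al. 1984"
Ictalurus punctatus,2-Ethoxyethyllacetate,21000,-4200,0.946,2900,,,"Holcombe et al. 1984"
Channa punctatus,Carbosulfan,1600,-1000,0.830,2000,,,"Nwani et al. 2010"
Channa punctatus,Glyphosate,41000,-7400,0.769,2000,,,"Nwani et al. 2010"
Channa punctatus,Atrazine,63000,-16000,0.958,2000,,,"Nwani et al. 2010"
Cyprinus carpio,Dichlorvos,37000,-1100,0.932,17160,,,"Das 2012"
Cyprinus carpio,Dimethoate,1900,-160,0.936,17160,,,"Singh et al. 2009"
Trichogaster trichopterus,Diazinon,40000,-18000,0.989,1500,,,"Hedayati et al. 2012"
Trichogaster trichopterus,Deltamethrin,300,-53,0.890,1500,,,"Hedayati et al. 2012"
Oncorhynchus mykiss,m-Cresol,8000,-3000,0.999,1300,,,"Capkin et al. 2010"
Oncorhynchus mykiss,Deltamethrin,4.5,-3.4,0.982,1300,,,"Ural and Saglam 2005"
Oncorhynchus mykiss,Endosulfan,19,-13,0.987,1300,,,"Capkin et al. 2006"
Gambusia affinis,m-Cresol,40000,-5600,0.894,700,,,"Sangli and Kanabur 2000"
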