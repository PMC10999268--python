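code,name,abbreviation,megabiome
1,tropical evergreen broadleaf forest,TrEB,tropical forest
2,tropical semi-evergreen broadleaf forest,TrSB,tropical forest
3,tropical deciduous broadleaf forest and woodland,TrDB,tropical forest
4,temperate deciduous broadleaf forest,TeDBF,temperate forest
5,temperate evergreen needleleaf forest,TeENF,temperate forest
6,cool mixed forest,CoM,temperate forest
7,cool evergreen needleleaf forest,CoEN,temperate forest
8,cool-temperate evergreen needleleaf and mixed forest,CoTeEN,temperate forest
9,warm-temperate evergreen broadleaf and mixed forest,WTeEB,warm-temperate forest
10,cold evergreen needleleaf forest,CdEN,boreal forest
11,cold deciduous forest,CdD,boreal forest
12,tropical savannah,TrS,savannah and dry woodland
13,temperate sclerophyll woodland and shrubland,TeS,savannah and dry woodland
14,temperate deciduous broadleaf savannah,TeDBS,savannah and dry woodland
15,temperate evergreen needleleaf open woodland,TeENW,savannah and dry woodland
16,tropical xerophytic shrubland,TrX,grassland and dry shrubland
17,temperate xerophytic shrubland,TeX,grassland and dry shrubland
18,cold parkland,CdP,grassland and dry shrubland
19,tropical grassland,TrG,grassland and dry shrubland
20,temperate grassland,TeG,grassland and dry shrubland
21,desert,De,desert
22,graminoid and forb tundra,GFTu,dry tundra
23,low and high shrub tundra,ShTu,tundra
24,erect dwarf-shrub tundra,EDTu,tundra
25,prostrate dwarf-shrub tundra,PDTu,tundra
26,cushion-forb tundra,CFTu,tundra
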