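rookery,subpopulation,region,longitude_deg
Iony Island,Sea of Okhotsk,eastern Russia,143.40
Yamsky Islands,Sea of Okhotsk,eastern Russia,155.55
Brat Chirpoev,Kuril Islands,eastern Russia,150.50
Antsiferov Island,Kuril Islands,eastern Russia,150.85
Srednego Rocks,Kuril Islands,eastern Russia,151.00
Raykoke Island,Kuril Islands,eastern Russia,153.25
Lovushki Islands,Kuril Islands,eastern Russia,153.85
Kozlov Cape,Kamchatka Peninsula,eastern Russia,161.73
Medny Island,Commander Islands,eastern Russia,167.60
Attu Island Cape Wrangell,western Aleutian Islands,Aleutian Islands,172.46
Agattu Island Gillon Point,western Aleutian Islands,Aleutian Islands,173.60
Buldir Island,western Aleutian Islands,Aleutian Islands,175.91
Kiska Island Lief Cove,central Aleutian Islands,Aleutian Islands,177.35
Amchitka Island Column Rock,central Aleutian Islands,Aleutian Islands,179.28
Ayugadak Point,central Aleutian Islands,Aleutian Islands,178.90
Ulak Island Hasgox Point,central Aleutian Islands,Aleutian Islands,-178.98
Gramp Rock,central Aleutian Islands,Aleutian Islands,-178.35
Tag Island,central Aleutian Islands,Aleutian Islands,-177.90
Adak Island Lake Point,central Aleutian Islands,Aleutian Islands,-176.57
Kasatochi Island,central Aleutian Islands,Aleutian Islands,-175.52
Seguam Island Saddleridge,central Aleutian Islands,Aleutian Islands,-172.57
Adugak Island,eastern Aleutian Islands,Aleutian Islands,-169.18
Bogoslof Island,eastern Aleutian Islands,Aleutian Islands,-168.03
Akutan Island Billings Head,eastern Aleutian Islands,Aleutian Islands,-165.60
Akun Island Billings Head,eastern Aleutian Islands,Aleutian Islands,-165.54
Ugamak Island,eastern Aleutian Islands,Aleutian Islands,-164.79
Sea Lion Rock Amak,eastern Aleutian Islands,Aleutian Islands,-163.20
Clubbing Rocks,western Gulf of Alaska,Gulf of Alaska,-162.43
Pinnacle Rock,western Gulf of Alaska,Gulf of Alaska,-161.76
Jude Island,western Gulf of Alaska,Gulf of Alaska,-161.06
Chernabura Island,western Gulf of Alaska,Gulf of Alaska,-159.57
Atkins Island,western Gulf of Alaska,Gulf of Alaska,-159.28
Chowiet Island,central Gulf of Alaska,Gulf of Alaska,-156.70
Chirikof Island,central Gulf of Alaska,Gulf of Alaska,-155.62
Sugarloaf Island,central Gulf of Alaska,Gulf of Alaska,-151.87
Marmot Island,central Gulf of Alaska,Gulf of Alaska,-151.80
Outer Island,eastern Gulf of Alaska,Gulf of Alaska,-150.40
Chiswell Island,eastern Gulf of Alaska,Gulf of Alaska,-149.58
Wooded Island,eastern Gulf of Alaska,Gulf of Alaska,-147.40
Seal Rocks,eastern Gulf of Alaska,Gulf of Alaska,-146.82
Graves Rock,northern Southeast Alaska,Southeast Alaska,-136.72
White Sisters,northern Southeast Alaska,Southeast Alaska,-135.80
Hazy Island,southern Southeast Alaska,Southeast Alaska,-134.62
Forrester Island Complex,southern Southeast Alaska,Southeast Alaska,-133.52
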