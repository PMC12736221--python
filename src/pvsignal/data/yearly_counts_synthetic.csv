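drug,year,count
stiripentol,2016,30
stiripentol,2017,45
stiripentol,2018,60
stiripentol,2019,75
stiripentol,2020,85
stiripentol,2021,100
stiripentol,2022,115
stiripentol,2023,129
stiripentol,2024,183
cannabidiol,2019,150
cannabidiol,2020,700
cannabidiol,2021,1065
cannabidiol,2022,800
cannabidiol,2023,757
cannabidiol,2024,750
fenfluramine,2020,90
fenfluramine,2021,150
fenfluramine,2022,190
fenfluramine,2023,209
fenfluramine,2024,213
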