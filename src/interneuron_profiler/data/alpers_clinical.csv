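case,sex,onset_age,death_age,seizures,developmental_delay,cortical_visual_impairment,liver_dysfunction,ataxia_hypotonia,variant_cdna,variant_protein,family_history
P01,M,2 m,5.5 m,+,+,+,,+,Unknown,Unknown,Affected sister
P02,M,4 m,13 m,+,+,+,+,+,Unknown,Unknown,
P03,F,11 m,14 m,+,+,,+,+,c.1399G>A/c.2542G>A,p.[Ala467Thr]/p.[Gly848Ser],
P04,M,6 m,17 m,+,+,,+,,Unknown,Unknown,
P05,F,12 m,18 m,+,+,+,+,+,Unknown,Unknown,
P06,M,18 m,2.8y,+,+,+,,,Unknown,Unknown,Affected sister
P07,F,2 m,4.0y,+,+,+,,,Unknown,Unknown,
P08,F,6 m,7.0y,+,+,+,+,+,c.2243G>C/c.2243G>C,p.[Trp748Ser]/p.[Trp748Ser],
P09,M,2y,11.9y,+,+,+,+,+,c.1399G>A/c.2542G>A,p.[Ala467Thr]/p.[Gly848Ser],Affected brother
P10,M,6y,12.5y,+,,+,,+,Unknown,Unknown,
P11,F,6 m,14.0y,+,+,+,,+,Unknown,Unknown,Affected brother
P12,F,18.0y,23.0y,+,,+,+,+,c.1399G>A/c.1399G>A,p.[Ala467Thr]/p.[Ala467Thr],
P13,F,20.0y,24.0y,+,,+,,+,c.1399G>A/c.2243G>C,p.[Ala467Thr]/p.[Trp748Ser],
P14,F,16.0y,28.0y,+,,+,,+,c.1399G>A/c.2243G>C,p.[Ala467Thr]/p.[Trp748Ser],Affected brother
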