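gene,subfamily
Kcna1,Kv
Kcna2,Kv
Kcna3,Kv
Kcna4,Kv
Kcna5,Kv
Kcna6,Kv
Kcna7,Kv
Kcna10,Kv
Kcnb1,Kv
Kcnb2,Kv
Kcnc1,Kv
Kcnc2,Kv
Kcnc3,Kv
Kcnc4,Kv
Kcnd1,Kv
Kcnd2,Kv
Kcnd3,Kv
Kcnf1,Kv
Kcng1,Kv
Kcng2,Kv
Kcng3,Kv
Kcng4,Kv
Kcnq1,Kv
Kcnq2,Kv
Kcnq3,Kv
Kcnq4,Kv
Kcnq5,Kv
Kcns1,Kv
Kcns2,Kv
Kcns3,Kv
Kcnv1,Kv
Kcnv2,Kv
Kcnh1,Kv
Kcnh2,Kv
Kcnh3,Kv
Kcnh4,Kv
Kcnh5,Kv
Kcnh6,Kv
Kcnh7,Kv
Kcnh8,Kv
Kcnma1,KCa
Kcnn1,KCa
Kcnn2,KCa
Kcnn3,KCa
Kcnn4,KCa
Kcnt1,KCa
Kcnt2,KCa
Kcnu1,KCa
Kcnj1,Kir
Kcnj2,Kir
Kcnj3,Kir
Kcnj4,Kir
Kcnj5,Kir
Kcnj6,Kir
Kcnj8,Kir
Kcnj9,Kir
Kcnj10,Kir
Kcnj11,Kir
Kcnj12,Kir
Kcnj13,Kir
Kcnj14,Kir
Kcnj15,Kir
Kcnj16,Kir
Kcnj18,Kir
Kcnk1,K2P
Kcnk2,K2P
Kcnk3,K2P
Kcnk4,K2P
Kcnk5,K2P
Kcnk6,K2P
Kcnk7,K2P
Kcnk9,K2P
Kcnk10,K2P
Kcnk12,K2P
Kcnk13,K2P
Kcnk15,K2P
Kcnk16,K2P
Kcnk17,K2P
Kcnk18,K2P
Cacna1a,Cav
Cacna1b,Cav
Cacna1c,Cav
Cacna1d,Cav
Cacna1e,Cav
Cacna1f,Cav
Cacna1g,Cav
Cacna1h,Cav
Cacna1i,Cav
Cacna1s,Cav
Scn1a,Nav
Scn2a,Nav
Scn3a,Nav
Scn4a,Nav
Scn5a,Nav
Scn7a,Nav
Scn8a,Nav
Scn9a,Nav
Scn10a,Nav
Scn11a,Nav
Catsper1,CatSper-TPC
Catsper2,CatSper-TPC
Catsper3,CatSper-TPC
Catsper4,CatSper-TPC
Tpcn1,CatSper-TPC
Tpcn2,CatSper-TPC
Cnga1,CNG
Cnga2,CNG
Cnga3,CNG
Cnga4,CNG
Cngb1,CNG
Cngb3,CNG
Hcn1,HCN
Hcn2,HCN
Hcn3,HCN
Hcn4,HCN
Trpa1,TRP
Trpc1,TRP
Trpc2,TRP
Trpc3,TRP
Trpc4,TRP
Trpc5,TRP
Trpc6,TRP
Trpc7,TRP
Trpm1,TRP
Trpm2,TRP
Trpm3,TRP
Trpm4,TRP
Trpm5,TRP
Trpm6,TRP
Trpm7,TRP
Trpm8,TRP
Trpv1,TRP
Trpv2,TRP
Trpv3,TRP
Trpv4,TRP
Trpv5,TRP
Trpv6,TRP
Mcoln1,TRP
Mcoln2,TRP
Mcoln3,TRP
Pkd2,TRP
Pkd2l1,TRP
Pkd2l2,TRP
Pkd1l3,TRP
Hvcn1,Hv
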