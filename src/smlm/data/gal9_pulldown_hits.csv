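uniprot,gene,log_e,log_l,pct_measured,pct_corrected,unique_peptides,total_peptides,mr,ratio
Q8VDN2,Atp1a1,-165.4,5.7,17,31,12,29,112.9,0.256864482
Q8C129,Lnpep,-119.5,5.58,11,23,10,21,117.2,0.179180887
P06800,Ptprc,-114.7,5.7,29.2,17,11,25,144.5,0.173010381
P24668,M6pr,-75.3,5.8,21,36,5,16,31.2,0.512820513
Q03265,Atp5a1,-70.2,5.33,18,24,7,12,59.7,0.201005025
P11835,Itgb2,-63.2,4.98,6.8,9,4,7,84.8,0.08254717
P19437,Ms4a1,-60.9,5.7,12,26,5,25,31.9,0.78369906
P10852,Slc3a2,-59.2,5.34,13,21,5,12,62.2,0.192926045
Q8BG07,Pld4,-52.3,5.3,16,32,5,11,56.1,0.196078431
P01872,Ighm,-39.3,5.3,8.6,16,3,9,50,0.18
Q62192,Cd180,-36.1,5.19,6.7,14,4,9,74.3,0.121130552
P51881,Slc25a5,-32.7,5.77,7,10,3,8,32.9,0.243161094
Q61735,Cd47,-25.6,5.39,7.7,26,2,11,35.3,0.311614731
P15530,Cd79b,-18.8,5.11,7.6,22,2,7,32.1,0.218068536
O35424,H2-Ob,-15.4,5.18,6.6,10,2,6,30.4,0.197368421
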