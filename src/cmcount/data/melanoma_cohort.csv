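patient_id,survival_months,alive_at_analysis,n_cmc_slide,cv_percent,n_cmc_ml,braf_status,sex,site,marker
1,5.5,True,4,50,21,positive,F,cutaneous,MelanA
2,4.6,True,10,32,27,positive,F,cutaneous,MelanA
3,31.9,True,79,11,78,positive,F,cutaneous,S100B
4,3.0,False,47,15,125,positive,M,cutaneous,MelanA
5,2.0,False,31,18,165,positive,M,cutaneous,S100B
6,27.8,False,101,10,287,negative,F,cutaneous,MelanA
7,0.5,False,75,12,400,unknown,F,uveal,MelanA
8,33.2,True,42,15,467,unknown,M,mucosal,S100B
9,28.9,True,304,5.7,1013,positive,F,cutaneous,S100B
10,4.5,False,1646,2.5,1568,unknown,M,mucosal,MelanA
11,1.0,False,2134,2.2,28483,positive,M,cutaneous,MelanA
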