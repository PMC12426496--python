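table,row_id,drug_label,indication,option_group,setting,outcome_measure,gain_value,gain_unit,follow_up_years,age_dx_years,crossover,toxicity_grade3plus,esmo_mcbs,course_cost_usd,cost_per_ly_usd,gdp_fraction,n_patients,annual_cost_usd,in_printed_total,deescalation
1,trastuzumab_6m_early_breast,Trastuzumab (6 months),Adjuvant treatment of non-metastatic breast cancer,her2_early_breast_adjuvant,curative,OS,0.065,proportion,10,47,false,0.03,A,1502,1156,0.3,880,1322000,true,true
1,trastuzumab_12m_early_breast,Trastuzumab (12 months),Adjuvant treatment of non-metastatic breast cancer,her2_early_breast_adjuvant,curative,OS,0.065,proportion,10,47,false,0.08,,2951,2270,0.6,880,2597161,false,false
1,rituximab_maintenance_fl,Rituximab (Maintenance),Follicular lymphoma,rituximab_maintenance_fl,palliative,PFS,79,months,,,false,0.10,Not scored,1550,795,0.06,50,76748,true,false
1,bortezomib_mm_1l,Bortezomib,Multiple myeloma (first line),bortezomib_mm_1l,palliative,OS,13.3,months,,,false,0.30,Not scored,485,437,0.11,475,230216,true,false
1,abiraterone_250_mhspc,Abiraterone 250 mg,Metastatic hormone sensitive prostate cancer,abiraterone_mhspc,palliative,OS,16.8,months,,,false,0.20,4,945,675,0.18,500,472447,true,true
1,abiraterone_250_mcrpc_post_docetaxel,Abiraterone 250 mg,Metastatic castration resistant prostate cancer (post-docetaxel),abiraterone_mcrpc_post_docetaxel,palliative,OS,3.9,months,,,false,0.20,4,289,1198,0.23,100,28943,true,true
1,rituximab_chemo_nhl,Rituximab (with chemotherapy),Non-Hodgkin's lymphoma,rituximab_chemo_nhl,palliative,OS,13,months,,,false,0.10,Not scored,1034,530,0.14,750,775235,true,false
1,gefitinib_egfr_lung_1l,Gefitinib,Metastatic adenocarcinoma of lung (first line),egfr_lung_1l,palliative,PFS,5.4,months,,,false,0.30,4,447,994,0.26,340,134240,false,false
1,abiraterone_250_mcrpc_pre_docetaxel,Abiraterone 250 mg,Metastatic castration resistant prostate cancer (pre-docetaxel),abiraterone_mcrpc_pre_docetaxel,palliative,OS,4.4,months,,,false,0.20,4,502,1370,0.36,300,150672,true,true
1,erlotinib_egfr_lung_1l,Erlotinib,Metastatic adenocarcinoma of lung (first line),egfr_lung_1l,palliative,OS,8.5,months,,,false,0.15,4,1003,2314,0.37,340,340902,true,false
1,lenalidomide_mm_ti_1l,Lenalidomide,Multiple myeloma (transplant ineligible first line),lenalidomide_mm_ti_1l,palliative,OS,13.2,months,,,false,0.30,Not scored,1704,1550,0.41,475,809629,true,false
1,trastuzumab_mbc,Trastuzumab,Metastatic breast cancer,trastuzumab_mbc,palliative,OS,4.8,months,,,false,0.08,Not assessed,2146,1764,0.46,264,566653,true,false
1,pomalidomide_mm_2l,Pomalidomide,Multiple myeloma (second line),pomalidomide_mm_2l,palliative,OS,4.4,months,,,false,0.15,Not assessed,1055,1809,0.47,333,350879,true,false
1,abiraterone_1000_mhspc,"Abiraterone 1,000 mg",Metastatic hormone sensitive prostate cancer,abiraterone_mhspc,palliative,OS,16.8,months,,,false,0.20,4,3780,2700,0.71,500,1889789,false,false
1,abiraterone_1000_mcrpc_post_docetaxel,"Abiraterone 1,000 mg",Metastatic castration resistant prostate cancer (post-docetaxel),abiraterone_mcrpc_post_docetaxel,palliative,OS,3.9,months,,,false,0.20,4,1158,3562,0.93,100,115771,false,false
1,cabazitaxel_mcrpc_post_docetaxel,Cabazitaxel,Metastatic castration resistant prostate cancer (post-docetaxel),cabazitaxel_mcrpc_post_docetaxel,palliative,OS,2.6,months,,,false,0.50,3,774,3573,0.94,100,77423,true,false
1,fulvestrant_250_mbc_1l,Fulvestrant 250,Metastatic breast cancer (first line) with anastrozole,fulvestrant_250_mbc_1l,palliative,OS,7.8,months,,,false,0.20,Not assessed,2433,3743,0.98,330,802938,true,false
2,osimertinib_lung_adjuvant,Osimertinib,Adjuvant treatment of resected stage IIB-III EGFR mutant adenocarcinoma of lung,osimertinib_lung_adjuvant,curative,DFS,0.50,proportion,3,64.5,false,,A,29692,6252,1.64,55,1633036,true,false
2,goserelin_prostate_adjuvant,Goserelin,Adjuvant treatment of localised prostate cancer with radical radiotherapy,goserelin_prostate_adjuvant,curative,DSS,0.048,proportion,10,62,false,,Not scored,1536,6399,1.68,300,460764,true,false
2,olaparib_brca_breast_adjuvant,Olaparib,Adjuvant treatment of germline BRCA mutant early breast cancer,olaparib_brca_breast_adjuvant,curative,DFS,0.088,proportion,3,42.5,false,,A,21746,7845,2.06,110,2392052,true,false
2,topotecan_cervical_2l,Topotecan,Metastatic cervical cancer (second line),topotecan_cervical_2l,palliative,OS,2.9,months,,,false,,Not scored,1015,4201,1.1,110,111672,true,false
2,sunitinib_mrcc_1l,Sunitinib,Metastatic renal cell carcinoma,mrcc_1l,palliative,OS,14,months,,,false,,4,5619,4816,1.26,100,561900,true,false
2,sunitinib_gist_2l,Sunitinib,Advanced gastrointestinal stromal tumour (second line),sunitinib_gist_2l,palliative,OS,20.9,months,,,false,,3,504992,5268,1.38,10,35120,true,false
2,trastuzumab_gastric,Trastuzumab,Metastatic adenocarcinoma of stomach,trastuzumab_gastric,palliative,OS,2.7,months,,,false,,3,1222,5433,1.42,65,79454,true,false
2,abiraterone_1000_mcrpc_pre_docetaxel,"Abiraterone 1,000 mg",Metastatic castration resistant prostate cancer (pre-docetaxel),abiraterone_mcrpc_pre_docetaxel,palliative,OS,4.4,months,,,false,0.20,4,289,5479,1.44,300,602689,false,false
2,fulvestrant_500_mbc_2l,Fulvestrant 500 mg,Metastatic breast cancer (second line),fulvestrant_500_mbc_2l,palliative,OS,4.1,months,,,false,,Not assessed,502,5997,1.57,440,901545,true,false
2,pazopanib_mrcc_1l,Pazopanib,Metastatic renal cell carcinoma,mrcc_1l,palliative,OS,14,months,,,false,,4,7780,6669,1.75,100,778000,false,false
2,bevacizumab_ovarian_pr,Bevacizumab,Platinum refractory advanced epithelial ovarian cancer,bevacizumab_ovarian_pr,palliative,OS,3.3,months,,,false,,4,2046,7442,1.95,285,583247,true,false
2,everolimus_mrcc_2l,Everolimus,Advanced renal cell carcinoma (second line),everolimus_mrcc_2l,palliative,OS,3,months,,,false,,3,1003,8814,2.31,40,88143,true,false
2,nab_paclitaxel_pancreatic_1l,Nab-Paclitaxel,Unresectable pancreatic cancer,nab_paclitaxel_pancreatic_1l,palliative,OS,2.4,months,,,false,,2,2180,10063,2.64,135,294337,true,false
2,pazopanib_sts_2l,Pazopanib,Metastatic soft tissue sarcoma (second line),pazopanib_sts_2l,palliative,OS,3,months,,,false,,3,2640,10559,2.77,26,68634,true,false
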