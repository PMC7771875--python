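subject_id,sex,age,gene_status,idh_status,mgmt_status,histology,who_grade,group,initial_dx,aptw_mean,aptw_max,aptw_min,excluded,exclusion_reason
1,M,63,"IDHwt, MGMT meth",wildtype,methylated,Glioblastoma,4,HGG,HGG,2.37,2.61,2.08,False,
2,F,51,"IDHwt, unknown MGMT status",wildtype,unknown,Glioblastoma,4,HGG,HGG,3.43,3.89,2.90,False,
3,M,48,"IDHwt, unknown MGMT status",wildtype,unknown,Astrocytoma,2,LGG,LGG,1.72,1.98,1.09,False,
4,M,57,"IDHwt, unknown MGMT status",wildtype,unknown,Glioblastoma,4,HGG,LGG,2.09,3.00,0.83,False,
5,M,43,"IDH mut, MGMT meth",mutant,methylated,Glioblastoma,4,HGG,HGG,2.30,2.88,1.75,False,
6,M,72,"IDHwt, MGMT meth",wildtype,methylated,Glioblastoma,4,HGG,MET,2.33,2.77,1.41,False,
7,M,52,"IDHwt, unknown MGMT status",wildtype,unknown,Glioblastoma,4,HGG,HGG,0.92,1.48,0.14,False,
8,M,30,"IDH mut, unknown MGMT status",mutant,unknown,Glioblastoma,4,HGG,HGG,5.08,5.83,3.93,False,
9,M,57,"IDH mut, 1p19q-codeletion, unknown MGMT status",mutant,unknown,Oligodendroglioma,2,LGG,LGG,0.88,1.21,0.41,False,
10,M,52,"IDH mut, MGMT meth",mutant,methylated,Glioblastoma,4,HGG,MET,2.25,2.88,1.61,False,
11,M,55,"IDH status unknown, 1p19q-codeletion, MGMT unknown",unknown,unknown,Oligodendroglioma,2,LGG,LGG,2.20,2.35,1.93,False,
12,M,53,"IDH mut, unknown MGMT status",mutant,unknown,Oligoastrocytoma,2,LGG,LGG,1.74,2.23,1.36,True,radiological progression after histological sampling
13,M,73,"IDHwt, MGMT meth",wildtype,methylated,Glioblastoma,4,HGG,MET,4.24,4.86,2.79,False,
14,M,43,"IDH mut, unknown MGMT status",mutant,unknown,Diffuse astrocytoma,2,LGG,LGG,1.68,2.06,1.27,False,
15,F,53,"IDHwt, GFAP+, MGMT non meth",wildtype,non-methylated,Glioblastoma,4,HGG,LGG,2.07,3.08,1.25,False,
16,M,46,"IDH and MGMT status unknown",unknown,unknown,Oligodendroglioma,2,LGG,LGG,2.28,2.86,1.54,True,radiological progression after histological sampling
17,M,62,"IDH mut, GFAP+, no 1p19q-codeletion, deletion within 19q, MGMT meth",mutant,methylated,Diffuse astrocytoma,2,LGG,LGG,0.94,2.11,0.02,False,
18,M,31,"IDH mut, unknown MGMT status",mutant,unknown,Glioblastoma,4,HGG,LGG,2.98,3.80,2.35,False,
19,M,63,"IDHwt, MGMT meth",wildtype,methylated,Glioblastoma,4,HGG,HGG,2.16,2.62,1.07,False,
20,M,61,"IDHwt, MGMT meth",wildtype,methylated,Glioblastoma,4,HGG,HGG,2.07,2.65,1.65,False,
21,F,68,"IDHwt, MGMT meth",wildtype,methylated,Glioblastoma,4,HGG,HGG,2.29,2.98,1.57,False,
22,F,71,"IDH status unknown, MGMT meth",unknown,methylated,Glioblastoma,4,HGG,MET,2.80,3.21,2.28,False,
23,M,26,"IDHwt, MGMT non meth",wildtype,non-methylated,Anaplastic astrocytoma,3,HGG,LGG,2.14,3.12,1.40,False,
24,M,48,"IDHwt, MGMT non meth",wildtype,non-methylated,Diffuse astrocytoma,2,LGG,LGG,1.54,1.96,1.34,False,
25,M,65,not assessed,unknown,unknown,Adenocarcinoma (GI origin),,MET,MET,2.25,2.77,1.31,True,metastasis: group too small for statistical analysis
26,M,76,not assessed,unknown,unknown,Adenocarcinoma (GI origin),,MET,MET,2.72,3.19,2.21,True,metastasis: group too small for statistical analysis
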