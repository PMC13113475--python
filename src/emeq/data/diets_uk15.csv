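diet_id,cohort,mei_mj_d,cp_pct,fa_pct,ee_pct,ndf_pct,adf_pct,forage_pct
1,lactating,222.3,18.5,3,6.4,32.5,26.65,50
2,lactating,271.7,17.98,3.56,4.12,32.78,26.88,53.36
3,lactating,218.7,22.05,4.5,6.2,33.05,27.1,50
4,lactating,262.6,15.6,4.33,4.14,34.87,28.59,69.2
5,lactating,268.9,16.05,3.74,4.7,35.15,28.82,50.51
6,lactating,255.2,17.43,3.91,4.07,35.47,29.09,57.69
7,lactating,210.6,17.4,3.5,6,37.25,30.55,50
8,lactating,207,16.2,7.5,5.85,37.5,30.75,50
9,lactating,203.4,19.75,4.5,5.65,38.05,31.2,50
10,lactating,222.3,19.25,0,5.1,38.85,31.86,50
11,lactating,207,16.95,0,4.55,43.85,35.96,50
12,lactating,196.2,15.2,2.5,5.45,45,36.9,50
13,lactating,202.3,18.08,3.41,4.32,46.11,37.81,81.89
14,dry,136.5,12.58,1.58,2.74,49.16,40.31,73.86
15,dry,125.3,13.97,1.73,3.41,52.5,43.05,81.44
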