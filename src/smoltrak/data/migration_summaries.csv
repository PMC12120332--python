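river,year,migration_success,rate_per_km,mean_speed_km_day,sd_speed_km_day
Aberdeenshire Dee,2019,0.645,0.996,8.59,3.56
Agivey,2021,0.657,0.984,7.23,5.00
Bladnoch,2021,0.730,0.903,4.76,9.39
Bladnoch,2022,0.761,0.949,12.24,10.00
Burrishoole,2021,0.821,0.941,13.93,27.26
Bush,2019,0.804,0.911,17.69,14.64
Bush,2020,0.909,0.960,14.20,11.16
Bush,2021,0.961,0.983,10.47,10.01
Bush,2022,0.968,0.986,9.18,10.30
Cassley,2021,0.682,0.990,3.38,1.33
Conon,2019,0.902,0.982,16.60,26.62
Conon,2021,0.647,0.964,9.25,18.36
Crawick,2021,0.774,0.994,10.86,9.29
Derwent (released at tagging site),2020,0.313,0.976,7.09,3.57
Derwent (released at tagging site),2021,0.327,0.977,3.31,1.53
Derwent (transported),2021,0.718,0.986,5.53,3.94
Derwent (transported),2022,0.515,0.972,3.31,2.61
Deveron,2019,0.514,0.989,4.65,1.72
Deveron,2021,0.740,0.996,7.03,3.13
Deveron,2022,0.115,0.974,1.64,0.0
Endrick,2020,0.333,0.968,3.05,1.98
Endrick,2021,0.135,0.942,3.03,1.36
Findhorn,2019,0.438,0.911,9.36,9.91
Findhorn,2021,0.863,0.972,58.98,43.83
Kirkcudbrightshire Dee,2021,0.225,0.968,3.02,0.89
Gryffe,2021,0.929,0.989,3.15,3.90
Gryffe,2022,0.837,0.979,1.99,1.49
Leven,2021,0.377,0.750,15.92,13.66
Leven,2022,0.889,0.989,8.76,12.28
Ness,2019,0.102,0.959,4.42,2.05
Ness,2021,0.198,0.972,2.79,1.05
Ness,2022,0.625,0.988,3.77,2.93
Nith,2021,0.825,0.985,10.72,21.14
Nith,2022,0.742,0.987,5.24,3.57
Orchy,2022,0.375,0.847,4.40,4.72
Oykel,2019,0.704,0.989,5.97,2.94
Oykel,2021,0.841,0.994,4.72,1.88
Oykel,2022,0.468,0.975,5.27,2.67
Scaur,2022,0.632,0.986,4.96,2.95
Shin,2019,0.918,0.992,2.76,6.50
Shin,2021,0.823,0.982,2.21,6.45
Spey,2019,0.610,0.990,7.03,3.33
Spey,2021,0.411,0.980,9.74,5.36
Spey,2022,0.034,0.972,6.68,2.12
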