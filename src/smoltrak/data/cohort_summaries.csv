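river,year,latitude,longitude,tag_type,n_tagged,date_tagged,mean_fork_length_mm,sd_fork_length_mm,mean_mass_g,sd_mass_g,mean_condition,sd_condition,mean_tag_burden_pct,sd_tag_burden_pct
Aberdeenshire Dee,2019,56.933,-3.420,V5-1x,105,01/04-28/04,133,7.32,24.3,4.05,0.034,0.055,2.7,0.4
Agivey,2021,54.988,-6.666,V7-2x,41,20/04,151,9.77,36.0,7.49,0.030,0.101,4.4,1.0
Bladnoch,2021,54.867,-4.498,V7-2x,127,20/04-15/05,142,7.28,29.1,4.67,0.022,0.053,5.3,0.8
Bladnoch,2022,54.867,-4.498,V7-2x,100,25/04-03/05,142,6.31,29.1,4.14,0.011,0.071,5.6,0.7
Burrishoole,2021,53.914,-9.571,"V7-2x, V8-4x, V7D-2x",85,05/05-11/05,184,23.91,71.5,29.50,0.074,0.108,3.0,1.2
Bush,2019,55.203,-6.523,V7-4x,49,18/04-02/05,157,8.82,38.4,5.36,0.002,0.078,4.8,0.6
Bush,2020,55.203,-6.523,V7-4x,100,15/04-13/05,169,11.26,45.5,5.64,-0.047,0.147,4.0,0.5
Bush,2021,55.203,-6.523,V7-4x,80,13/04-26/04,169,9.85,48.5,9.89,0.007,0.076,3.8,0.6
Bush,2022,55.203,-6.523,V7-4x,100,05/04-30/04,171,8.51,52.1,7.70,0.051,0.081,3.5,0.5
Cassley,2021,58.143,-4.780,V7-2x,47,26/04-04/05,140,6.28,25.2,3.91,-0.090,0.082,6.1,0.9
Conon,2019,57.553,-4.593,V7-2x,99,14/04-07/05,139,5.39,26.6,3.35,-0.016,0.044,5.7,0.7
Conon,2021,57.553,-4.593,V7-2x,100,16/04-07/05,145,8.56,30.0,5.53,-0.028,0.061,5.1,0.8
Crawick,2021,55.378,-3.931,V7-2x,49,15/04-23/04,138,5.17,26.8,2.76,0.021,0.063,5.7,0.6
Derwent (released at tagging site),2020,54.611,-3.062,V7-2x,100,01/05-03/05,139,6.49,27.9,4.25,0.030,0.096,5.5,0.8
Derwent (released at tagging site),2021,54.611,-3.062,V7-2x,93,16/04-05/05,142,8.39,29.5,5.56,0.026,0.059,5.5,1.0
Derwent (transported),2021,54.688,-3.298,V7-2x,57,20/04-04/05,141,7.63,29.7,5.11,0.057,0.048,5.5,0.9
Derwent (transported),2022,54.688,-3.298,V7-2x,115,05/05-25/05,139,6.65,27.4,4.14,0.027,0.055,5.6,0.7
Deveron,2019,57.363,-3.028,"V7-2x, V7D-2x",100,13/04-30/04,134,5.04,23.5,2.66,-0.013,0.058,6.7,0.6
Deveron,2021,57.363,-3.028,"V7-2x, V7D-2x",100,13/04-30/04,137,4.83,25.1,2.96,-0.022,0.060,6.0,0.7
Deveron,2022,57.363,-3.028,"V7-2x, V6-2x",100,04/04-30/04,137,6.88,25.3,3.94,-0.018,0.069,4.8,1.3
Endrick,2020,56.049,-4.440,V7-2x,158,13/04-20/04,146,17.73,32.2,15.07,-0.005,0.098,5.1,1.2
Endrick,2021,56.049,-4.440,V7-2x,99,15/04-04/05,143,10.12,29.5,6.33,0.010,0.069,5.3,1.0
Findhorn,2019,57.595,-3.659,V7-2x,100,14/04-16/05,135,6.05,23.6,3.58,-0.051,0.052,6.5,0.9
Findhorn,2021,57.595,-3.659,V7-2x,93,13/04-02/05,137,6.62,23.7,3.16,-0.082,0.062,6.4,0.7
Kirkcudbrightshire Dee,2021,55.134,-4.193,V7-2x,50,17/04-23/05,148,11.23,32.0,6.88,-0.028,0.054,4.9,1.2
Gryffe,2021,55.869,-4.494,V7-2x,101,14/04-26/04,149,10.17,34.0,6.69,0.024,0.076,4.6,0.9
Gryffe,2022,55.869,-4.494,V7-2x,122,12/04-24/04,142,6.51,28.7,4.2,-0.001,0.084,5.3,0.9
Leven,2021,56.009,-4.590,V7-2x,46,13/04-01/05,148,10.35,32.6,6.75,-0.001,0.119,4.8,0.9
Leven,2022,56.009,-4.590,V7-2x,178,14/04-06/05,143,7.52,30.1,4.84,0.027,0.070,5.1,0.8
Ness,2019,57.071,-4.773,"V7-2x, V7D-2x",100,12/04-26/04,140,10.91,28.8,6.73,0.035,0.063,5.6,0.9
Ness,2021,57.071,-4.773,V7-2x,120,06/04-30/04,140,7.88,28.2,5.10,0.027,0.065,5.5,0.9
Ness,2022,57.071,-4.773,"V6-2x, V7D-2x",74,05/04-23/04,142,9.20,30.3,6.12,0.057,0.048,4.1,1.2
Nith,2021,55.176,-3.729,V7-2x,130,23/04-06/05,148,10.85,33.7,7.10,0.004,0.074,4.8,1.0
Nith,2022,55.176,-3.729,V7-2x,100,18/04-30/04,146,11.65,31.9,8.23,0.014,0.052,5.3,1.2
Orchy,2022,56.404,-5.157,V7-2x,26,29/04-01/05,143,8.28,27.7,5.18,-0.052,0.076,5.9,0.9
Oykel,2019,57.994,-4.803,V7-2x,149,11/04-03/05,137,7.24,25.3,3.94,-0.017,0.058,6.1,0.8
Oykel,2021,57.994,-4.803,V7-2x,100,16/04-27/04,140,7.47,25.7,4.28,-0.066,0.043,6.0,0.9
Oykel,2022,57.994,-4.803,V6-2x,50,09/04-22/04,142,9.06,27.9,5.91,-0.028,0.062,3.3,0.5
Scaur,2022,55.217,-3.781,V7-2x,75,14/04-23/04,140,8.71,27.7,5.92,0.014,0.041,6.0,0.9
Shin,2019,58.010,-4.399,V7-2x,100,11/04-27/04,136,4.83,24.2,2.50,-0.038,0.054,6.2,0.6
Shin,2021,58.010,-4.399,V7-2x,100,16/04-24/04,140,6.63,25.7,3.60,-0.067,0.058,5.9,0.8
Spey,2019,57.416,-3.377,V7-2x,150,13/04-02/05,134,3.59,24.0,2.46,-0.010,0.059,6.3,0.6
Spey,2021,57.416,-3.377,V7-2x,100,14/04-02/05,135,4.10,24.2,2.37,-0.022,0.050,6.2,0.6
Spey,2022,57.416,-3.377,"V7D-2x, V6-2x",126,04/04-07/05,138,5.98,27.1,3.90,0.050,0.218,3.9,0.9
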