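species,generation,season,year,total,mean_per_shoot,incidence
Andricus inflator,sexual,spring,2008,52,0.0022,0.0018
Andricus inflator,sexual,spring,2009,0,0,0
Andricus testaceipes,sexual,spring,2008,973,0.041,0.0025
Andricus testaceipes,sexual,spring,2009,2291,0.095,0.067
Biorhiza pallida,sexual,spring,2008,13,0.00054,0.00046
Biorhiza pallida,sexual,spring,2009,10,0.00042,0.00042
Neuroterus albipes,sexual,spring,2008,822,0.034,0.03
Neuroterus albipes,sexual,spring,2009,5828,0.24,0.16
Neuroterus anthracinus,sexual,spring,2008,14278,0.59,0.35
Neuroterus anthracinus,sexual,spring,2009,7411,0.31,0.23
Neuroterus numismalis,sexual,spring,2008,1154,0.048,0.039
Neuroterus numismalis,sexual,spring,2009,17486,0.73,0.29
Neuroterus quercusbaccarum,sexual,spring,2008,5808,0.24,0.15
Neuroterus quercusbaccarum,sexual,spring,2009,7834,0.33,0.2
Andricus callidoma,asexual,autumn,2008,4,0.00021,0.00021
Andricus callidoma,asexual,autumn,2009,45,0.0019,0.0018
Andricus fecundatrix,asexual,autumn,2008,334,0.017,0.013
Andricus fecundatrix,asexual,autumn,2009,1103,0.046,0.029
Andricus glandulae,asexual,autumn,2008,83,0.0043,0.0037
Andricus glandulae,asexual,autumn,2009,335,0.014,0.012
Andricus inflator,asexual,autumn,2008,44,0.0023,0.002
Andricus inflator,asexual,autumn,2009,3,0.00013,0.00013
Andricus kollari,asexual,autumn,2008,2,0.0001,0.0001
Andricus kollari,asexual,autumn,2009,43,0.0018,0.0012
Andricus solitarius,asexual,autumn,2008,528,0.028,0.026
Andricus solitarius,asexual,autumn,2009,726,0.03,0.028
Cynips divisa,asexual,autumn,2008,1901,0.099,0.057
Cynips divisa,asexual,autumn,2009,184,0.0077,0.0057
Cynips longiventris,asexual,autumn,2008,1,0.000052,0.000052
Cynips longiventris,asexual,autumn,2009,3,0.00013,0.00013
Cynips quercusfolii,asexual,autumn,2008,197,0.01,0.0085
Cynips quercusfolii,asexual,autumn,2009,456,0.019,0.013
Neuroterus albipes,asexual,autumn,2008,45771,2.38,0.51
Neuroterus albipes,asexual,autumn,2009,27531,1.15,0.32
Neuroterus anthracinus,asexual,autumn,2008,313507,16.33,0.93
Neuroterus anthracinus,asexual,autumn,2009,23820,0.99,0.29
Neuroterus numismalis,asexual,autumn,2008,12194,0.64,0.037
Neuroterus numismalis,asexual,autumn,2009,12124,0.51,0.028
Neuroterus quercusbaccarum,asexual,autumn,2008,123708,6.44,0.56
Neuroterus quercusbaccarum,asexual,autumn,2009,94830,3.95,0.49
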