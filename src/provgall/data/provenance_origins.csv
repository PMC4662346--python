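code,name,country,longitude,latitude,altitude,genotyped,mean_budburst,mean_dbh,mean_form,is_local
185,Blakeney,UK,-2.5,51.78,76,False,1.08,120,4.24,False
217,Berce,France,0.39,47.81,155,True,1.59,98,4.2,True
237,Reno Valdieu,France,0.67,48.5,230,True,1.65,116,4.14,False
210,Saint Germain,France,2.08,48.9,60,True,1.71,113,4.13,False
194,Soudrain,France,2.38,46.95,178,True,1.24,110,4.33,False
211,Premery,France,3.6,47.2,300,True,1.55,106,4.34,False
201,La Haie Renaut,France,4.95,48.67,180,True,1.77,109,4.24,False
245,Etangs,France,4.96,46.93,200,True,2.4,113,4.19,False
233,Vacheres,France,5.63,43.98,650,True,3.69,94,4.15,False
230,Romersberg,France,6.73,48.82,220,False,1.06,101,4.17,False
250,Cochem,Germany,7.05,50.08,400,True,1.86,112,4.43,False
225,Still,France,7.25,48.58,688,True,1.55,105,4.56,False
252,Johanneskreuz,Germany,7.83,49.4,460,True,1.03,116,4.42,False
257,Wolfgang,Germany,9.05,50.15,160,True,1.61,96,3.92,False
181,Horbylunde,Denmark,9.41,56.13,80,True,0.88,89,3.99,False
255,Spakensehl,Germany,10.6,52.8,115,True,0.54,102,4.74,False
248,Kloster-marienberg,Austria,16.57,47.41,310,True,3.23,103,3.9,False
179,Sycow,Poland,17.93,51.18,210,True,1.42,104,4.76,False
249,Bolu,Turkey,31.67,40.92,1200,True,1.58,94,4.39,False
184,Telavi,Georgia,45.47,41.88,700,False,3.79,77,3.06,False
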