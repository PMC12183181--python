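site,age,sex,f0,f1,f2,f3,f4,f5
site0,0.304717079754,0,-1.60438615859,0.732876618769,-1.55515741153,-0.321513325641,-0.05246127146,0.00807838372957
site0,-1.03998410624,0,-0.219378885326,0.0779332818837,-1.02371365374,-1.47640993341,-0.0115691814729,-1.13893966244
site0,0.750451195806,1,-1.43137741984,-0.487447218426,-0.522226043774,1.63491362917,0.84600407146,0.50420970814
site0,0.940564716391,1,0.0130028821556,0.584604971995,0.794831030779,0.607614345988,1.57796080276,-0.49050094247
site0,-1.95103518865,1,-2.10207683817,-0.950620243853,-1.82886864841,-0.330203919483,-2.66277775421,-1.10075029832
site0,-1.30217950686,1,-0.313647464621,-0.0595929146675,-0.0737133555723,-0.707118477605,-2.00032258183,-0.917041379405
site0,0.127840403167,1,-2.53813988759,-0.970669210613,-1.09603681124,-0.97244637185,0.749537251115,-1.00465794755
site0,-0.316242592344,1,-0.873862595922,0.980597959,-0.498262341635,1.21184760672,-2.03134339678,-0.626505503232
site0,-0.0168011575043,1,-1.52011073944,-0.170034434276,0.582857770533,-2.13106406909,0.682186527213,-0.157458915013
site0,-0.853043927574,0,-2.07467463555,-1.58086072872,-0.610692999205,-1.43839191305,-0.962400367377,-0.896363128708
site1,0.879397974863,1,2.39197450302,0.625736436636,0.418479461541,0.314264696322,0.811789306877,2.30355635812
site1,0.777791935429,0,1.17298649657,0.853374005864,2.49806599959,-0.991346756542,-0.342449487688,-0.19621686821
site1,0.0660306975612,0,-0.551424115728,-1.08464017867,1.34530325714,-0.527496976808,-1.47417098926,-0.618018667474
site1,1.12724120697,1,1.1218555476,1.74007331678,3.47959373265,2.48555327229,1.11531538911,0.194182066079
site1,0.467509342252,0,-2.23295957151,0.626777841632,0.130892617962,-0.521720493296,-0.464005628605,0.401707121518
site1,-0.859292462883,0,0.531925731147,-0.0911887811658,0.122038159541,-1.4968015682,-2.10970318357,-0.554864989317
site1,0.368750784082,1,0.307493885182,2.25073195447,1.29320022106,0.730625449311,-0.117489373952,-0.350654109712
site1,-0.958882600829,1,-1.41075261568,-0.677451761107,2.59233834283,-1.14399422963,0.525127076503,-0.712645231476
site1,0.878450301307,0,1.33311276473,0.926100710889,0.969907201036,-0.0811099459239,-0.308798228713,1.15293194777
site1,-0.0499259109863,1,-0.358510225194,-0.720026598534,-0.281631369589,-0.0437668265262,1.66461470496,0.726024600455
site2,-0.184862363545,1,0.180993983744,0.271266568331,1.51560081185,0.856956384082,-0.13940227706,2.11124394186
site2,-0.680929544404,1,0.483554664292,1.27317974106,0.329010918903,-0.945485264769,-1.32144327518,2.56204993611
site2,1.22254133867,0,2.45100469894,0.209622026089,0.402859976464,2.61026273524,-0.42618422923,-0.316487003827
site2,-0.154529482069,0,0.6632250225,-0.694014545867,0.134111602307,0.145669135039,0.315331405473,2.13610861517
site2,-0.428327822163,0,-0.0337867673236,0.207645418868,-1.75462301973,0.122045453723,-0.976981418965,-2.06362438557
site2,-0.352133550488,0,-0.974373382484,-0.732335544718,0.845842068338,-1.19853211097,-0.0825952822479,-0.889148480046
site2,0.532309185553,1,0.332143358313,1.34680218198,1.16130291632,2.43004653672,0.463754320504,-0.0829290494175
site2,0.365444064364,0,0.0495365764723,0.203089283225,0.516439478757,-0.558479706184,0.327984799567,0.738930273134
site2,0.412732611596,1,3.14727150613,2.16111442533,-0.0948360738273,0.635398279367,-0.878595995383,-0.0138544334762
site2,0.430821003008,1,0.931010238171,1.4991564578,0.020467450427,0.254304194431,-1.54039588459,0.650464268685
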