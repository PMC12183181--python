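"f0","f1","f2","f3","f4","f5"
-0.779091485959,1.077731791359,-0.926550084571,-0.074209302382,-0.01200683156,0.7859463601
0.666777936027,0.421522791104,-0.269942607792,-1.232724774164,0.009623974244,-0.567794182203
-0.617063165414,-0.085395019118,0.147558863978,1.80750759911,0.883642188823,1.22558945552
0.864376053892,0.960194402639,1.620056811124,0.896426530067,1.606250459222,-0.072390048958
-1.261628681123,-0.574301872282,-1.202906067872,-0.1993861917,-2.605076807049,-0.593664854641
0.565829443404,0.30169591373,0.742020754716,-0.48376566989,-1.944490159768,-0.416478287682
-1.744311805367,-0.564307579938,-0.470261439501,-0.600098956749,0.780145487611,-0.660016371561
-0.026334892985,1.327582888324,0.221362085326,1.333652373474,-1.961371576607,-0.132579563986
-0.695541326196,0.212497156905,1.423778645967,-1.658578298984,0.711896974933,0.443898229621
-1.243270532233,-1.189498627363,0.186230123793,-1.182295018597,-0.923064069063,-0.27259027696
2.043546016905,0.558375034551,0.006583504879,0.406390432922,0.716741588957,2.1658060429
0.900172322005,0.713099529178,1.665519873157,-0.922753659138,-0.392967700252,-0.359327152173
-0.709448530584,-1.102159959068,0.655302640647,-0.39799514624,-1.49183080537,-0.783714331883
0.898579338809,1.595531983979,2.597433825373,2.686247995551,1.01443673117,0.027477344618
-2.221434805633,0.49157542847,-0.34462310155,-0.411698174374,-0.523237035353,0.24781457582
0.229607892777,-0.224367394278,-0.42619752849,-1.375587044384,-2.136430264419,-0.715830202803
0.116216357348,2.035178220116,0.714442101937,0.87109910639,-0.181692909706,-0.521375511204
-1.520172619896,-0.717841894056,1.733957247012,-1.042330258955,0.351597395435,-0.882568315596
1.051457131792,0.784242166463,0.384659664503,0.033156760346,-0.356131507503,1.0072498928
-0.51301471578,-0.71992943039,-0.634721751659,0.074275107649,1.468069676484,0.571312055591
-0.395269893923,-0.011678148191,1.412894188508,0.479687951899,-0.158944852675,1.416460848575
-0.105007467282,1.033710195124,0.221661399103,-1.242922127955,-1.318534272392,1.734317008797
1.839097317255,-0.078353379258,0.295261837168,2.15694422265,-0.412580434521,-0.503474272305
0.071209655498,-0.988379247764,0.027512798844,-0.234783257027,0.27286806577,1.317660797543
-0.614823878065,-0.050699866263,-1.869448523053,-0.271243537039,-0.98822060714,-1.983667949834
-1.535136301255,-1.024466958825,0.74283107696,-1.51049740062,-0.118261537344,-1.060461237392
-0.238443135121,1.08804598239,1.055806819416,1.997866905937,0.444295072762,-0.24855993543
-0.523490119085,-0.069692667605,0.410752643316,-0.870672896836,0.298079506325,0.26182826593
2.51733413373,1.93259106874,-0.205904875469,0.302147890016,-0.861523377733,-0.202883951113
0.346866311336,1.24747994619,-0.09010135478,-0.055680241267,-1.50339665141,0.317571493838
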