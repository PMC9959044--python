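std_order,run_order,x1_coded,x2_coded,x3_coded,alginate_pct,cacl2_pct,oil_pct,y1_ee_pct,y2_buoyancy_h,y3_q6h_pct
13,1,0.0,0.0,-1.6817928305,4.0,10.0,2.636414339,59,2.0,49
16,2,0.0,0.0,0.0,4.0,10.0,6.0,90,9.0,69
7,3,-1.0,1.0,1.0,2.0,15.0,8.0,66,8.0,35
3,4,-1.0,1.0,-1.0,2.0,15.0,4.0,41,2.5,28
1,5,-1.0,-1.0,-1.0,2.0,5.0,4.0,50,4.0,66
17,6,0.0,0.0,0.0,4.0,10.0,6.0,90,9.0,69
8,7,1.0,1.0,1.0,6.0,15.0,8.0,92,10.6,42
11,8,0.0,-1.6817928305,0.0,4.0,1.5910358475,6.0,56,6.2,75
9,9,-1.6817928305,0.0,0.0,0.636414339,10.0,6.0,51,3.3,55
6,10,1.0,-1.0,1.0,6.0,5.0,8.0,83,10.0,56
4,11,1.0,1.0,-1.0,6.0,15.0,4.0,77,2.6,36
14,12,0.0,0.0,1.6817928305,4.0,10.0,9.363585661,94,11.5,49
10,13,1.6817928305,0.0,0.0,7.363585661,10.0,6.0,90,7.0,48
12,14,0.0,1.6817928305,0.0,4.0,18.4089641525,6.0,63,7.5,25
2,15,1.0,-1.0,-1.0,6.0,5.0,4.0,63,4.5,59
5,16,-1.0,-1.0,1.0,2.0,5.0,8.0,68,7.0,65
15,17,0.0,0.0,0.0,4.0,10.0,6.0,90,9.0,69
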