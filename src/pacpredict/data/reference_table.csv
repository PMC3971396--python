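id,fs_hz,focus,n_channels,train_dur_h,train_n_seizures,sop_min,band,preictal_phase_rad,threshold_pct,train_ss_pct,train_fpr_per_h,test_dur_h,test_n_seizures,test_ss_pct,test_fpr_per_h,significant,power_significant
1,1024,f-r,98,126,4,60,LT,-2.62,30,75,0.38,120,6,100,2.04,0,---
2,1024,t-l,96,135,4,60,HT,1.38,21,100,0.60,82,4,50,2.21,0,---
3,1024,"tml,t-r",57,64,4,60,LD,0.81,30,75,0.44,55,9,11,0.18,0,---
4,1024,"tmr,tlr",117,108,4,60,HD,0.24,21,75,0.36,75,5,20,0.37,0,---
5,1024,tlr,38,171,3,60,HT,0.81,11,67,0.14,80,2,50,0.64,0,---
6,1024,tml,74,99,4,60,LD,-0.90,19,100,0.45,63,5,100,0.72,1,---
7,1024,t-l,46,85,4,60,HD,-2.62,11,75,0.59,163,5,80,4.35,0,---
8,1024,"t-l,f-l",115,42,4,60,LT,-2.05,21,75,0.42,86,8,63,0.44,0,---
9,1024,tmr,62,16,4,60,HD,1.95,19,75,0.11,139,10,20,0.46,0,---
10,1024,"fbr,tm-",124,104,4,60,LT,-2.05,15,75,0.22,48,3,33,6.02,0,---
11,1024,f-r,48,25,4,60,LT,-2.05,11,75,0.11,116,8,13,0.35,0,-**
12,256,tll,40,70,4,60,LD,1.95,22,100,0.10,129,13,54,1.11,0,---
13,1024,f-r,93,35,4,30,LD,0.24,44,100,0.10,89,11,73,0.30,1,---
14,1024,f-l,89,123,4,60,HD,2.52,30,100,0.30,122,12,75,0.77,0,*--
15,1024,"o-r,t-l",114,29,4,60,LT,2.52,18,100,0.27,85,6,17,0.30,0,---
16,1024,"tlr,tmr",69,18,4,60,HT,1.95,36,75,0.09,153,11,73,0.43,1,---
17,1024,"tml,t-l",83,34,4,60,HT,-2.05,27,75,0.08,109,18,22,0.13,0,---
18,1024,"tmr,tlr",46,23,3,60,HD,2.52,42,100,0.06,201,10,40,0.33,0,---
19,1024,"f-l,c-l",83,25,4,60,HT,-2.05,7,75,0.24,85,13,31,1.72,0,---
20,1024,tml,84,79,4,60,LD,-2.62,50,100,0.06,346,32,56,0.10,1,*--
21,256,tmr,54,61,4,60,HT,-2.05,19,100,0.30,164,18,6,0.31,0,---
22,256,"tbl,tll,--b",41,96,4,60,LT,2.86,39,75,0.36,71,2,0,0.33,0,---
23,512,"tml,t--",39,143,4,60,LD,1.38,25,75,0.52,21,2,50,0.71,0,---
24,256,t-b,28,42,3,60,HT,2.86,47,67,0.22,92,2,0,1.37,0,---
25,256,"tml,tll,t-r",42,156,4,60,LT,2.52,39,100,0.68,41,3,67,1.31,0,---
26,256,"t--,f-l",36,72,4,60,HD,-1.48,25,75,0.46,108,16,63,2.35,0,---
27,256,fml,47,180,4,60,LD,0.81,36,100,0.41,49,4,100,0.63,1,---
28,256,tbr,96,74,4,60,HD,2.52,10,75,0.19,125,13,62,1.59,0,---
29,256,"tml,tll",84,87,4,60,HT,1.95,47,75,0.14,136,6,0,0.02,0,---
30,400,tpr,52,390,4,60,HT,-1.48,27,100,0.41,74,3,67,0.27,0,---
31,400,f-l,58,27,4,30,LT,-2.05,24,75,0.13,168,21,10,0.17,0,---
32,400,fpl,38,210,3,60,HT,-0.90,36,100,0.44,136,2,100,1.17,0,---
33,400,tml,42,117,3,60,HD,-2.05,22,100,0.33,120,2,100,2.22,0,---
34,400,tmr,49,197,3,60,LT,-2.05,22,100,0.10,154,2,50,0.14,0,---
35,400,t-r,51,124,3,60,HD,1.38,22,100,0.52,213,2,100,1.69,0,---
36,400,tml,56,145,3,60,LD,-2.05,22,67,0.07,14,2,100,2.70,0,**-
37,400,tpr,48,177,4,60,HD,0.81,16,75,0.12,168,5,60,0.56,0,---
38,400,o--,42,407,2,60,LT,1.38,22,100,0.20,37,2,0,0.03,0,---
39,400,tml,32,155,4,30,HD,-1.48,22,75,0.25,69,3,0,0.31,0,---
40,400,tlr,41,109,4,60,LD,0.81,19,75,0.39,39,4,50,2.31,0,---
41,400,"t-r,o-r",34,198,4,60,LD,-0.33,28,75,0.04,145,4,0,0.13,0,---
42,400,f-r,28,62,3,60,LD,1.38,23,67,0.09,152,8,38,0.08,1,---
43,400,p-r,33,170,4,60,LT,0.24,31,75,0.12,15,2,50,1.61,0,---
44,400,tbr,32,508,2,30,HD,2.52,47,100,0.09,51,2,0,0.35,0,---
45,1024,"fbr,tmr",41,17,4,60,LD,-2.62,36,75,0.35,301,11,27,0.10,0,---
46,1024,"fbr,tml",29,82,4,60,HD,-0.90,34,75,0.12,185,11,36,0.08,1,---
47,1024,"h-l,fpl",63,131,3,60,HD,0.24,30,100,0.09,268,2,0,0.03,0,---
48,1024,tmr,63,180,4,60,LD,1.95,24,100,0.41,265,4,100,1.79,0,---
49,1024,tlr,60,403,2,60,LD,0.24,24,100,0.19,53,2,50,0.47,0,---
50,1024,tm-,56,196,4,60,LT,2.52,24,75,0.16,291,9,0,0.15,0,---
51,512,t-l,25,31,3,60,LD,-0.33,28,67,0.28,104,2,100,0.66,0,---
52,1024,p-l,39,42,2,60,HD,0.24,42,100,0.29,42,2,50,0.48,0,---
53,512,f-r,10,149,3,60,LD,-2.62,31,100,0.15,42,2,50,0.80,0,*--
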