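chip_id,name,R,G,B,L,a_star,b_star
1,dark_skin,115,82,68,38.02,11.8,13.67
2,light_skin,194,150,130,65.67,13.67,16.9
3,blue_sky,98,122,157,50.63,0.37,-21.6
4,foliage,87,108,67,43.0,-15.88,20.45
5,blue_flower,133,128,177,55.68,12.76,-25.17
6,bluish_green,103,189,170,70.99,-30.64,1.54
7,orange,214,126,44,61.14,28.1,56.13
8,purplish_blue,80,91,166,41.12,17.41,-41.88
9,moderate_red,193,90,99,51.33,42.1,14.89
10,purple,94,60,108,31.1,24.35,-22.1
11,yellow_green,157,188,64,71.9,-28.1,56.96
12,orange_yellow,224,163,46,71.04,12.6,64.92
13,blue,56,61,150,30.35,26.43,-49.67
14,green,70,148,73,55.03,-40.14,32.3
15,red,175,54,60,41.35,49.3,24.66
16,yellow,231,199,31,80.7,-3.66,77.55
17,magenta,187,86,149,51.14,48.15,-15.28
18,cyan,8,133,161,51.15,-19.73,-23.37
19,white_95,243,243,242,95.82,-0.18,0.49
20,neutral_8,200,200,200,80.6,-0.0,0.0
21,neutral_65,160,160,160,65.87,-0.0,0.0
22,neutral_5,122,122,121,51.19,-0.2,0.55
23,neutral_35,85,85,85,36.15,-0.0,0.0
24,black_2,52,52,52,21.7,-0.0,0.0
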