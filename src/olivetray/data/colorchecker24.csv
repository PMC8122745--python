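patch_index,patch_name,r,g,b
1,dark_skin,115,82,68
2,light_skin,194,150,130
3,blue_sky,98,122,157
4,foliage,87,108,67
5,blue_flower,133,128,177
6,bluish_green,103,189,170
7,orange,214,126,44
8,purplish_blue,80,91,166
9,moderate_red,193,90,99
10,purple,94,60,108
11,yellow_green,157,188,64
12,orange_yellow,224,163,46
13,blue,56,61,150
14,green,70,148,73
15,red,175,54,60
16,yellow,231,199,31
17,magenta,187,86,149
18,cyan,8,133,161
19,white_95,243,243,242
20,neutral_8,200,200,200
21,neutral_65,160,160,160
22,neutral_5,122,122,121
23,neutral_35,85,85,85
24,black_2,52,52,52
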