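No,T,H,THI,F,M,L,S,RS,RL,TOTAL_MIN
1,31.2,88.7,86.1,100,330,470,210,70,260,1440
2,31.3,85.4,85.7,100,300,450,140,170,280,1440
3,31.9,80.8,86.0,70,250,450,220,180,270,1440
4,32.0,76.1,85.3,70,240,480,200,170,280,1440
5,31.9,76.8,85.2,70,330,490,150,130,270,1440
6,32.0,77.1,85.5,130,190,600,150,160,210,1440
7,31.6,78.7,85.2,170,220,520,170,120,230,1430
8,31.6,78.6,85.0,130,320,380,210,170,230,1440
9,32.0,75.8,85.3,130,290,410,130,140,340,1440
10,31.9,79.2,85.7,170,310,390,150,70,350,1440
11,32.1,76.3,85.36,80,370,450,150,80,310,1440
12,32.2,73.9,85.2,160,370,480,50,90,290,1440
13,33.2,70.5,86.0,100,440,450,180,60,210,1440
14,32.3,73.7,85.4,140,440,380,210,100,170,1440
15,32.5,72.9,85.5,170,360,440,70,140,260,1440
16,31.7,74.9,84.7,210,510,340,160,70,150,1440
17,30.9,79.7,84.2,120,390,420,120,130,260,1440
18,32.0,77.0,85.4,160,430,470,90,100,190,1440
19,32.9,73.3,86.2,240,360,490,80,80,190,1440
20,31.1,80.9,84.8,260,360,430,110,20,260,1440
21,31.5,81.0,85.3,170,330,510,150,120,160,1440
22,31.4,80.6,85.1,180,380,490,90,50,250,1440
23,31.5,77.3,84.7,80,450,530,120,80,180,1440
24,30.4,81.6,83.6,70,400,550,130,70,220,1440
25,29.1,77.8,81.0,110,350,430,170,70,310,1440
26,29.6,73.2,81.2,70,290,560,160,110,250,1440
27,29.9,71.4,81.3,100,350,540,150,100,200,1440
28,30.1,74.7,82.1,120,370,510,130,80,230,1440
29,30.8,80.1,84.1,120,340,520,90,60,310,1440
30,31.2,82.2,85.1,70,360,490,160,130,230,1440
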