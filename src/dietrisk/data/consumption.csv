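food_id,demographic,ir_g_per_day
bear,girls,1.050
bear,boys,0.550
bear,women,0.900
bear,men,3.450
beaver,girls,1.280
beaver,boys,0.950
beaver,women,3.800
beaver,men,8.850
caribou,girls,1.350
caribou,boys,1.680
caribou,women,2.400
caribou,men,7.350
duck,girls,0.830
duck,boys,2.250
duck,women,5.750
duck,men,9.150
goose,girls,5.300
goose,boys,7.800
goose,women,13.50
goose,men,21.90
grouse,girls,1.100
grouse,boys,1.430
grouse,women,3.100
grouse,men,8.400
hare,girls,1.330
hare,boys,2.280
hare,women,5.150
hare,men,11.70
moose,girls,3.130
moose,boys,3.800
moose,women,12.80
moose,men,19.65
walleye,girls,0.780
walleye,boys,3.630
walleye,women,7.300
walleye,men,11.48
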