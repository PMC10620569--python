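species,group,summer_day,summer_night,winter_day,winter_night
bobcat,mesocarnivore,41,27,26,84
fisher,mesocarnivore,171,164,65,618
coyote,mesocarnivore,297,376,162,926
red_fox,mesocarnivore,105,94,100,416
gray_fox,mesocarnivore,57,78,7,171
long_tailed_weasel,mesocarnivore,32,448,1,134
white_tailed_deer,herbivore_small_mammal,3326,1705,1594,269
eastern_cottontail,herbivore_small_mammal,300,331,18,1130
gray_squirrel,herbivore_small_mammal,8368,185,11940,1306
red_squirrel,herbivore_small_mammal,2299,109,2277,238
eastern_chipmunk,herbivore_small_mammal,3166,10,870,32
striped_skunk,urban_adapted_omnivore,4,140,0,36
virginia_opossum,urban_adapted_omnivore,13,1022,1,232
raccoon,urban_adapted_omnivore,217,2052,30,2100
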