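alternative,label,location_km,age,access_healthcare,airways,consciousness,pulse,trauma,health_history,access_location,social_commotion
victim_1,Victim 1,12.4,22,2,4,1,1,1,4,1,3
victim_2,Victim 2,12.1,40,1,4,4,4,4,1,3,3
victim_3,Victim 3,11.8,23,3,3,4,3,4,1,3,2
victim_4,Victim 4,12,60,2,3,4,2,1,4,2,2
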