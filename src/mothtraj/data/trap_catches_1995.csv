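# Pheromone-trap captures of citrus pollen-marked Helicoverpa zea males,
# south-central Texas, 20-22 March 1995.  Dates are the morning the traps
# were checked; each record is matched to the flight released the previous
# evening (night = date - 1 day).
date,name,lon,lat,n_trapped,n_examined,n_pollen
1995-03-20,Falfurrias,-98.15,27.17,6,4,1
1995-03-20,Three Rivers,-98.18,28.43,2,2,1
1995-03-20,Karnes City,-97.85,28.92,19,2,2
1995-03-20,Belmont,-97.68,29.52,9,3,2
1995-03-20,Rockdale,-96.68,30.66,11,1,1
1995-03-20,Richland,-96.43,31.91,3,3,3
1995-03-21,Falfurrias,-98.15,27.17,10,2,2
1995-03-21,Alice,-98.08,27.80,2,1,1
1995-03-22,Falfurrias,-98.15,27.17,8,4,1
1995-03-22,Bastrop,-97.35,30.11,14,2,1
1995-03-22,Kosse,-96.64,31.29,14,2,1
1995-03-22,Richland,-96.43,31.91,8,3,3
1995-03-22,Rogers,-97.22,30.93,21,5,1
1995-03-22,Karnes City,-97.85,28.92,21,2,1
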