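# Synthetic life table: sex-specific remaining life expectancy e(age) at
# single years of age 15-100, built by monotone interpolation through
# anchor values on the scale of the 2016 US period life table. The female
# value at age 25 is pinned to 57.0 years (published tables give ~56.8)
# so that the package's worked-example arithmetic is internally exact.
# This fixture is a stand-in, not a transcription of the official table.
sex,age,life_expectancy_years
female,15,66.6
female,16,65.6
female,17,64.7
female,18,63.7
female,19,62.8
female,20,61.8
female,21,60.8
female,22,59.9
female,23,58.9
female,24,58.0
female,25,57.0
female,26,56.0
female,27,55.1
female,28,54.1
female,29,53.2
female,30,52.2
female,31,51.2
female,32,50.3
female,33,49.3
female,34,48.4
female,35,47.4
female,36,46.5
female,37,45.5
female,38,44.6
female,39,43.6
female,40,42.7
female,41,41.7
female,42,40.8
female,43,39.9
female,44,38.9
female,45,38.0
female,46,37.1
female,47,36.2
female,48,35.2
female,49,34.3
female,50,33.4
female,51,32.5
female,52,31.6
female,53,30.7
female,54,29.9
female,55,29.0
female,56,28.1
female,57,27.3
female,58,26.4
female,59,25.6
female,60,24.8
female,61,23.9
female,62,23.1
female,63,22.3
female,64,21.5
female,65,20.7
female,66,19.9
female,67,19.1
female,68,18.3
female,69,17.5
female,70,16.7
female,71,15.9
female,72,15.2
female,73,14.4
female,74,13.7
female,75,13.0
female,76,12.3
female,77,11.7
female,78,11.0
female,79,10.4
female,80,9.7
female,81,9.1
female,82,8.6
female,83,8.0
female,84,7.5
female,85,7.0
female,86,6.5
female,87,6.1
female,88,5.7
female,89,5.3
female,90,4.9
female,91,4.5
female,92,4.1
female,93,3.8
female,94,3.5
female,95,3.2
female,96,2.9
female,97,2.7
female,98,2.5
female,99,2.3
female,100,2.1
male,15,62.2
male,16,61.3
male,17,60.3
male,18,59.4
male,19,58.5
male,20,57.5
male,21,56.6
male,22,55.7
male,23,54.8
male,24,53.8
male,25,52.9
male,26,52.0
male,27,51.0
male,28,50.1
male,29,49.2
male,30,48.3
male,31,47.4
male,32,46.4
male,33,45.5
male,34,44.6
male,35,43.7
male,36,42.8
male,37,41.9
male,38,41.0
male,39,40.1
male,40,39.2
male,41,38.3
male,42,37.4
male,43,36.5
male,44,35.7
male,45,34.8
male,46,33.9
male,47,33.1
male,48,32.2
male,49,31.4
male,50,30.5
male,51,29.7
male,52,28.9
male,53,28.0
male,54,27.2
male,55,26.4
male,56,25.6
male,57,24.8
male,58,24.0
male,59,23.2
male,60,22.4
male,61,21.7
male,62,20.9
male,63,20.2
male,64,19.4
male,65,18.7
male,66,18.0
male,67,17.3
male,68,16.5
male,69,15.8
male,70,15.1
male,71,14.5
male,72,13.8
male,73,13.1
male,74,12.5
male,75,11.9
male,76,11.3
male,77,10.7
male,78,10.1
male,79,9.5
male,80,9.0
male,81,8.4
male,82,7.9
male,83,7.4
male,84,6.9
male,85,6.5
male,86,6.1
male,87,5.7
male,88,5.3
male,89,4.9
male,90,4.5
male,91,4.2
male,92,3.9
male,93,3.6
male,94,3.3
male,95,3.0
male,96,2.7
male,97,2.5
male,98,2.3
male,99,2.1
male,100,1.9
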