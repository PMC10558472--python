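power_w,duration_min,length_mm,diameter_mm
80.0,3.0,37.5,31.5
80.0,4.0,39.6,34.2
80.0,5.0,41.7,36.1
80.0,6.0,43.3,38.3
80.0,7.0,44.9,39.8
80.0,8.0,46.4,41.5
80.0,9.0,47.6,43.0
80.0,10.0,48.9,44.1
90.0,3.0,37.9,31.8
90.0,4.0,39.9,34.7
90.0,5.0,42.1,36.7
90.0,6.0,43.6,38.7
90.0,7.0,45.3,40.3
90.0,8.0,46.8,42.0
90.0,9.0,47.9,43.4
90.0,10.0,49.3,44.8
100.0,3.0,38.2,32.3
100.0,4.0,40.3,35.0
100.0,5.0,42.4,37.2
100.0,6.0,43.9,39.1
100.0,7.0,45.7,40.8
100.0,8.0,47.1,42.5
100.0,9.0,48.3,43.7
100.0,10.0,49.7,45.3
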