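month,tmax_c,tmin_c,rain_mm,rhmax_pct,rhmin_pct,wind_kmh,sunshine_h,epan_mm
1,19.5,7.3,1.7,95.0,51.1,4.09,8.5,3.5
2,20.1,8.3,3.0,94.2,51.0,4.18,8.6,3.9
3,21.2,10.3,23.8,93.8,53.4,5.18,8.6,4.3
4,22.1,12.0,69.5,93.1,57.6,4.57,7.7,4.1
5,21.8,12.6,226.0,93.9,63.5,4.54,6.7,3.4
6,18.5,12.0,814.9,95.9,78.2,7.20,5.3,2.5
7,17.6,11.8,753.6,96.2,80.3,8.51,3.0,2.1
8,17.7,11.8,447.6,95.9,78.5,7.59,3.4,2.2
9,18.6,11.5,271.9,95.5,72.1,4.76,4.5,2.5
10,18.5,11.0,295.1,95.6,71.1,3.71,4.8,2.5
11,18.0,9.9,146.2,95.4,65.0,4.22,5.7,2.6
12,18.6,8.5,38.0,95.3,55.4,4.47,7.2,3.0
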