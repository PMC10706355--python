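unit_id,name,population,arable_ssr_pct,arable_demand_km2,arable_radius_km,horticultural_ssr_pct,horticultural_demand_km2,horticultural_radius_km,waters_ssr_pct,waters_demand_km2,waters_radius_km
guangzhou,Guangzhou,1867.66,11.47,17119.30,174.24,35.64,475.67,16.32,162.96,789.28,59.85
shenzhen,Shenzhen,1756.01,0.75,16095.85,198.23,5.46,447.24,20.45,22.99,742.10,67.27
foshan,Foshan,949.89,13.97,8706.82,107.42,85.22,241.93,24.53,13.69,401.43,39.82
zhaoqing,Zhaoqing,411.36,60.80,3770.59,84.99,234.23,104.77,6.22,462.65,173.84,54.93
dongguan,Dongguan,1046.66,2.70,9593.89,130.91,25.67,266.57,18.71,76.19,442.33,36.42
huizhou,Huizhou,604.29,48.21,5538.98,105.58,121.35,153.90,10.17,548.69,255.37,49.52
zhuhai,Zhuhai,243.96,10.85,2236.17,73.21,295.88,62.13,12.05,90.33,103.10,9.23
zhongshan,Zhongshan,441.81,12.03,4049.67,85.71,102.39,112.52,10.85,47.30,186.71,18.95
jiangmen,Jiangmen,479.81,61.58,4398.01,78.33,386.11,122.20,8.22,262.31,202.77,33.51
prd,PRD,7801.43,16.73,71509.28,397.06,214.96,1986.94,40.97,84.13,3296.93,143.56
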