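unit_id,name,population
guangzhou,Guangzhou,1867.66
shenzhen,Shenzhen,1756.01
foshan,Foshan,949.89
zhaoqing,Zhaoqing,411.36
dongguan,Dongguan,1046.66
huizhou,Huizhou,604.29
zhuhai,Zhuhai,243.96
zhongshan,Zhongshan,441.81
jiangmen,Jiangmen,479.81
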