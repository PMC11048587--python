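subject,sex,age,token,spl_db,f0_hz,flow_ccps,psub_cmh2o
1,male,33,soft,74,110,210,3
1,male,33,modal,85,109,170,5
1,male,33,loud,88,110,110,7
2,male,29,soft,70,102,79,4
2,male,29,modal,83,121,132,5
2,male,29,loud,89,139,89,8
3,male,69,soft,85,125,100,2
3,male,69,modal,91,123,220,3
3,male,69,loud,100,136,170,7
4,female,64,soft,74,161,100,4
4,female,64,modal,84,157,110,5.3
4,female,64,loud,87,186,130,10
5,female,24,soft,76,212,100,6
5,female,24,modal,85,215,80,9
5,female,24,loud,90,217,60,15
6,female,30,soft,75,168,130,4.6
6,female,30,modal,86,182,130,7
6,female,30,loud,92,207,120,11.2
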