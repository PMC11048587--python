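subject,token,resistance,db_change,resistance_change,resistance_change_per_db
1,soft,14.28571,,,
1,modal,29.41176,11,15.12605,1.375095
1,loud,63.63636,3,34.2246,11.4082
2,soft,50.63291,,,
2,modal,37.87879,13,-12.7541,-0.98109
2,loud,89.88764,6,52.00885,8.668142
3,soft,20,,,
3,modal,13.63636,6,-6.36364,-1.06061
3,loud,41.17647,9,27.54011,3.060012
4,soft,40,,,
4,modal,48.18182,10,8.181818,0.818182
4,loud,76.92308,3,28.74126,9.58042
5,soft,60,,,
5,modal,112.5,9,52.5,5.833333
5,loud,250,5,137.5,27.5
6,soft,35.38462,,,
6,modal,53.84615,11,18.46154,1.678322
6,loud,93.33333,6,39.48718,6.581197
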