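id,sex,age,duration_years,chd,la_volume_ml,aa_pre,rf_duration_s,relapse,aa_post
1,F,51,2,One vessel CHD,99,Sotalol,56,"Yes, re-PVI",Sotalol
2,M,55,10,No CHD,122,Beta blocker,41,"Yes, re-PVI",Beta blocker
3,F,67,7,No CHD,123,"Beta blocker, dronedarone",61,"Yes, re-PVI","Beta blocker, dronedarone"
4,M,44,13,No CHD,72,Beta blocker,40,None,"Beta blocker, flecainide"
5,F,56,4,No CHD,118,"Beta blocker, flecainide",79,None,"Beta blocker, flecainide"
6,M,54,1,No CHD,76,"Beta blocker, flecainide",61,None,"Beta blocker, flecainide"
7,M,72,17,No CHD,82,"Beta blocker, dronedarone",69,None,"Beta blocker, dronedarone"
8,M,69,3,three vessel CHD,183,Beta blocker,98,"Yes, re-PVI","Beta blocker, dronedarone"
9,M,64,2,No CHD,125,"Beta blocker, flecainide",91,None,"Beta blocker, propafenone"
10,F,49,5,No CHD,82,"Beta blocker, flecainide",81,None,"Beta blocker, flecainide"
11,M,48,1,No CHD,116,"Beta blocker, dronedarone",43,None,Dronedarone
12,F,70,2,No CHD,N/A,"Beta blocker, dronedarone",40,"Yes, no re-PVI","Beta blocker, flecainide"
13,M,52,5,No CHD,103,"Beta blocker, flecainide",33,None,"Beta blocker, flecainide"
14,M,40,1,No CHD,52,Beta blocker,41,None,"Beta blocker, flecainide"
15,M,61,4,No CHD,115,"Beta blocker, flecainide",49,None,"Beta blocker, flecainide"
16,M,52,5,No CHD,103,"Beta blocker, flecainide",51,None,"Beta blocker, flecainide"
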