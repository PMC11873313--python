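trial_id,t_ms,x_m
T1,0,0.0
T1,100,0.05
T1,200,0.1
T1,300,0.15
T1,400,0.18
T1,500,0.2
T2,0,0.0
T2,150,0.02
T2,300,-0.05
T2,450,-0.1
T2,600,-0.14
T2,750,-0.18
T2,900,-0.2
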