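trial_id,participant,device,n_back,trial_type,rt_ms,accuracy
T1,P01,vr,1,match,500,1
T2,P01,vr,2,nonmatch,900,0
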