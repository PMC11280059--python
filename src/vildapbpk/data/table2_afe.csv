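group,parameter,afe
oral_healthy,cmax,1.03
oral_healthy,auc,1.21
oral_healthy,cl,1.23
renal_failure,cmax,1.15
renal_failure,auc,1.28
renal_failure,cl,1.30
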