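delay_ms,0,2,4,6,8,10,20,40,60,80
100,Ankle,Ankle,Ankle,Ankle,Ankle,Ankle,Knee,Knee,Knee,Knee
150,Ankle,Ankle,Ankle,Hip,Ankle,Ankle,Ankle,Ankle,Hip,Knee
200,Ankle,Ankle,Ankle/Hip,Ankle,Ankle,Ankle,Ankle,Knee,Ankle,Ankle
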