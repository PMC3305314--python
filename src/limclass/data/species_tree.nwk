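[&R] (Co,((Sr,Mb),(Aq,(Ml,(Ta,(Nv,(Dm,Hs)))))));
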