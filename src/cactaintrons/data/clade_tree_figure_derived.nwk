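(((alpha,(beta,gamma)bg)abg,(delta,epsilon)de)monoc,(zeta,(eta,theta)et)zet)root;
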