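# Worked-example parameter set bundled with the package.
A: 4.4236
d: 0.1
beta: 0.01
m: 0.1
gamma: 0.1
alpha: 0.3995
p: 0.01
k: 0.1
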