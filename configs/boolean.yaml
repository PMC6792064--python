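seed: 1
model: {name: boolean, n: 1000}
kernel: {variant: baseline, R: 10}
benchmark: {repetitions: 10, fractions: [0.05, 0.1, 0.2, 0.5, 1.0]}
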