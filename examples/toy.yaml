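label: toy-two-tasks
demands: [1, 1]
n_workers: 2
initial_allocation: all-idle
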