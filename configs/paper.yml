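# Full-scale configuration: the published optimisation recipe for this
# model family (Adam, lr 8e-5, weight decay 1e-4, cosine annealing, 100
# epochs, batch 128; N = K = 5 prototypes; all loss weights 0.9).
learning_rate: 8.0e-5
weight_decay: 1.0e-4
epochs: 100
batch_size: 128
schedule: cosine
L: 3
d_g: 64
d_t: 64
d_p: 64
N: 5
K: 5
lambda_align: 0.9
lambda_pred: 0.9
lambda_proto: 0.9
tau: 0.5
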