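# Desk-scale configuration: small dimensions and a short schedule so the
# full pipeline trains in seconds on one CPU.  The learning rate and batch
# size are scaled for the short schedule (about 200 optimiser steps on a
# few hundred records).
learning_rate: 3.0e-3
weight_decay: 1.0e-4
epochs: 20
batch_size: 32
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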