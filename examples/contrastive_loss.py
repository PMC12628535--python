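"""NT-Xent contrastive loss on analytically tractable batches.

Checks the implementation against closed forms: identical projections give
log(2N - 1); a single pair has no negatives, so zero loss; and sharper
temperatures reduce the loss of a well-separated batch.
"""

import numpy as np

from methylcl import ContrastiveBatch, ntxent_batch_loss
from methylcl.autodiff import Tensor

# N = 4 pairs, all 8 projections identical -> every view is equally similar
# to its partner and to the 6 negatives: loss = log(7)
batch = ContrastiveBatch(Tensor(np.ones((8, 16))), tau=0.5)
print("identical projections (N=4):", float(ntxent_batch_loss(batch).data))
print("log(2N-1) = log 7        :", np.log(7))

# N = 1: the denominator contains only the positive partner -> loss 0
single = ContrastiveBatch(Tensor(np.array([[1.0, 2.0], [0.5, 1.0]])), tau=0.5)
print("\nsingle pair loss:", float(ntxent_batch_loss(single).data))

# a separable batch: smaller temperature sharpens the softmax -> lower loss
Z = np.array([[1.0, 0, 0], [0.9, 0.1, 0], [0, 1.0, 0], [0, 0.9, 0.1]])
for tau in (1.0, 0.5, 0.1):
    loss = float(ntxent_batch_loss(ContrastiveBatch(Tensor(Z), tau=tau)).data)
    print(f"tau={tau:<4} loss={loss:.4f}")
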