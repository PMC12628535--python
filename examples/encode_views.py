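"""Encode one RNA window into its two model views.

Builds a short gap-padded window, shows the k-mer token stream consumed by
the primary branch and the chaos-game state vector consumed by the auxiliary
branch.
"""

import numpy as np

from methylcl import cgr_trace, kmerize, pad_sequence

seq = pad_sequence("GGACUACGUAGCCGUAAGCUUACG", target_len=41)
print(f"padded window ({len(seq)} nt): {seq}")

tokens = kmerize(seq, k=6)
print(f"\nprimary view: {len(tokens.tokens)} tokens (= 41 - 6 + 3)")
print("first five:", tokens.tokens[:5])
print("gap-containing k-mers map to [UNK]:", tokens.tokens[-3:])

trace = cgr_trace(seq)
print(f"\nauxiliary view: {len(trace.states)} chaos-game states in [-1, 1]")
print("first five states:", np.round(trace.states[:5], 4))
print("padded tail is frozen:", np.round(trace.states[-3:], 4))
# Each state is (y - x) of the walk p_i = p_{i-1} + 0.5 (vertex - p_{i-1});
# identical trailing values show that gap positions do not move the walk.
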