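"""Sub-state HMM decoding on a toy score matrix.

Builds the four-sub-state left-to-right HMM from a two-class syntax, feeds
it a small hand-made frame-score table (including a misleading burst of
sub-division-1 evidence inside a note), and prints the decoded annotation,
showing how the left-to-right constraints suppress spurious boundaries.
"""

import numpy as np

from songscribe import (
    SyntaxModel,
    build_substate_hmm,
    decode_frame_sequence,
    path_to_annotation,
)

model = SyntaxModel(["A", "B"], alpha=0.0, trans=np.full((2, 2, 2), 0.5))
hmm = build_substate_hmm(model)
print(f"{hmm.n_states} states for n=2 classes "
      "(contexts x {begin, middle, end, silence})")

# 7 output classes: A1 A2 A3 B1 B2 B3 silence; 14 frames of evidence for
# silence, then one note A whose middle contains a 1-frame burst of A1
frames = ["S", "S", "A1", "A1", "A2", "A1", "A2", "A2", "A3", "A3", "S", "S"]
index = {"A1": 0, "A2": 1, "A3": 2, "B1": 3, "B2": 4, "B3": 5, "S": 6}
em = np.full((7, len(frames)), 0.02)
for t, lab in enumerate(frames):
    em[index[lab], t] = 0.9

path = decode_frame_sequence(hmm, em)
ann = path_to_annotation(path)
print("frame evidence :", " ".join(f"{l:>2}" for l in frames))
print("decoded notes  :", [(n.onset, n.offset, n.label) for n in ann.notes])
print("-> one note despite the stray sub-division-1 frame at t=5: the")
print("   2 -> 1 transition is structurally forbidden, so no boundary forms.")
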