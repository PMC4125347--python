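"""Derive the bipolar montage from the 56-electrode reference layout.

48 electrodes sit on the forearm in an 8-around x 6-along grid and 8 more
on hand muscles in chains of 2, 3 and 3.  Differencing adjacent electrodes
along the fiber (proximal-distal) direction inside the grid and along each
hand chain yields the bipolar channel set.
"""

import numpy as np

from emgpick import ElectrodeLayout, apply_bipolar_montage, build_bipolar_pairs
from emgpick.recording import EmgRecording

layout = ElectrodeLayout(n_around=8, n_along=6, hand_groups=(2, 3, 3))
pairs = build_bipolar_pairs(layout)
print(f"{layout.n_electrodes} monopolar electrodes -> {len(pairs)} bipolar channels")
print("first grid pairs:", [(p.anode, p.cathode) for p in pairs[:3]])
print("hand-chain pairs:", [(p.anode, p.cathode) for p in pairs[-4:]])

rng = np.random.default_rng(0)
rec = EmgRecording(
    signal=rng.standard_normal((1024, layout.n_electrodes)),
    fs=1024.0,
    labels=np.zeros(1024, dtype=int),
)
bipolar = apply_bipolar_montage(rec, pairs)
print(f"monopolar recording {rec.signal.shape} -> bipolar {bipolar.signal.shape}")
# Each bipolar channel is (proximal - distal); common-mode activity shared by
# an electrode pair cancels, which is why bipolar montages often classify better.
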