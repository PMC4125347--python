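"""Electrode geometry and bipolar montage derivation.

The reference layout places 48 electrodes on the forearm in an
8-around x 6-along grid (the "along" axis runs proximal to distal,
parallel to the muscle fibers) plus three short chains on hand muscles
(first dorsal interosseous, thenar, hypothenar) of 2, 3 and 3
electrodes.  Monopolar channels are numbered grid-first in around-major
order, then hand chains in listed order.

Bipolar channels are differences between electrodes adjacent along the
fiber direction inside the grid and between consecutive electrodes
within each hand chain, giving ``n_around*(n_along-1) + sum(g-1)``
pairs — 45 for the reference layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import EmgRecording


@dataclass(frozen=True)
class BipolarPair:
    """One bipolar derivation: ``anode`` (proximal) minus ``cathode`` (distal)."""

    anode: int
    cathode: int

    def __post_init__(self) -> None:
        if self.anode == self.cathode:
            raise ValueError("bipolar pair must use two distinct electrodes")
        if self.anode < 0 or self.cathode < 0:
            raise ValueError("electrode indices must be non-negative")


@dataclass(frozen=True)
class ElectrodeLayout:
    """Forearm grid plus hand-muscle electrode chains.

    Parameters
    ----------
    n_around
        Electrodes around the limb circumference (grid rows).
    n_along
        Electrodes along the proximal-distal axis (grid columns).
    hand_groups
        Sizes of the hand-muscle electrode chains, in listed order.
    """

    n_around: int = 8
    n_along: int = 6
    hand_groups: tuple[int, ...] = (2, 3, 3)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hand_groups", tuple(int(g) for g in self.hand_groups))
        if self.n_around < 1 or self.n_along < 1:
            raise ValueError("grid dimensions must be >= 1")
        if any(g < 1 for g in self.hand_groups):
            raise ValueError("every hand group must contain >= 1 electrode")

    @property
    def n_grid(self) -> int:
        return self.n_around * self.n_along

    @property
    def n_electrodes(self) -> int:
        return self.n_grid + sum(self.hand_groups)

    def grid_channel(self, around: int, along: int) -> int:
        """Global channel index of grid electrode (around, along), around-major."""
        if not (0 <= around < self.n_around and 0 <= along < self.n_along):
            raise ValueError(f"grid position ({around}, {along}) outside layout")
        return around * self.n_along + along

    def hand_channels(self, group: int) -> list[int]:
        """Global channel indices of one hand chain, in chain order."""
        if not 0 <= group < len(self.hand_groups):
            raise ValueError(f"no hand group {group}")
        offset = self.n_grid + sum(self.hand_groups[:group])
        return list(range(offset, offset + self.hand_groups[group]))

    @classmethod
    def from_dict(cls, cfg: dict) -> "ElectrodeLayout":
        return cls(
            n_around=int(cfg["n_around"]),
            n_along=int(cfg["n_along"]),
            hand_groups=tuple(cfg.get("hand_groups", ())),
        )

    def to_dict(self) -> dict:
        return {
            "n_around": self.n_around,
            "n_along": self.n_along,
            "hand_groups": list(self.hand_groups),
        }


def build_bipolar_pairs(layout: ElectrodeLayout) -> list[BipolarPair]:
    """Enumerate the bipolar pairs of a layout.

    Grid pairs run along the proximal-distal axis (anode = proximal
    electrode), listed in around-major order; hand-chain pairs follow,
    consecutive within each chain.  The pair count is
    ``n_around*(n_along-1) + sum(g-1 for g in hand_groups)``.
    """
    pairs: list[BipolarPair] = []
    for a in range(layout.n_around):
        for l in range(layout.n_along - 1):
            pairs.append(
                BipolarPair(
                    anode=layout.grid_channel(a, l),
                    cathode=layout.grid_channel(a, l + 1),
                )
            )
    for g in range(len(layout.hand_groups)):
        chain = layout.hand_channels(g)
        for u, v in zip(chain[:-1], chain[1:]):
            pairs.append(BipolarPair(anode=u, cathode=v))
    return pairs


def apply_bipolar_montage(
    recording: EmgRecording, pairs: list[BipolarPair]
) -> EmgRecording:
    """Re-reference a monopolar recording to the given bipolar pairs.

    Output channel ``k`` is ``anode_k - cathode_k`` sample-wise; sample
    count, sampling rate and annotations are unchanged.
    """
    if not pairs:
        raise ValueError("no bipolar pairs given")
    d = recording.n_channels
    anodes = np.array([p.anode for p in pairs])
    cathodes = np.array([p.cathode for p in pairs])
    bad = np.concatenate((anodes[anodes >= d], cathodes[cathodes >= d]))
    if bad.size:
        raise ValueError(
            f"bipolar pair references channel {int(bad[0])} but the recording "
            f"has only {d} channels"
        )
    bipolar = recording.signal[:, anodes] - recording.signal[:, cathodes]
    return recording.with_signal(bipolar)
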