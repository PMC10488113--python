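"""In-memory containers for multi-channel slice images.

Channels are keyed by stain role (``"WGA"``, ``"RyR"``, ``"dextran"``,
``"DAPI"``, ``"lipofuscin"``, optionally ``"SERCA"``) and share a single
2D pixel grid with an isotropic physical pixel size in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator

import numpy as np

#: Stain roles the pipeline knows about.  WGA and RyR are required for a
#: full run; the remainder are optional.
CHANNEL_ROLES = ("WGA", "RyR", "dextran", "DAPI", "lipofuscin", "SERCA")

#: Default pixel size of the confocal scans this package targets (µm).
DEFAULT_PIXEL_SIZE_UM = 0.1


@dataclass
class MultiChannelImage:
    """A set of co-registered 2D intensity planes.

    Parameters
    ----------
    channels
        Mapping from stain role to a 2D integer or float intensity array.
        All arrays must share one shape.
    pixel_size_um
        Physical edge length of one (square) pixel in micrometres.
    """

    channels: Dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MultiChannelImage requires at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def __contains__(self, role: str) -> bool:
        return role in self.channels

    def __getitem__(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel {role!r} not present; available: {sorted(self.channels)}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)


def require_same_grid(*arrays: np.ndarray) -> None:
    """Raise ``ValueError`` unless all arrays share one 2D shape."""
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"arrays must share one grid, got shapes {shapes}")
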