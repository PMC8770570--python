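"""Multi-channel 3D image volume with voxel geometry and acquisition metadata.

`VoxelStack` is the carrier passed between every pipeline stage.  Arrays are
stored in (z, y, x) order with z increasing with depth into the tissue;
in-plane voxel size and z step are in micrometres, acquisition time in
seconds since dye injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

# canonical channel names used throughout the package
CH_SHG = "shg"
CH_GREEN = "green"
CH_RED = "red"
CH_BLUE = "blue"

DYE_CHANNELS = (CH_GREEN, CH_RED)

#: acquisition defaults (0.4 um/pixel in-plane, 3 um z step)
DEFAULT_VOXEL_XY = 0.4
DEFAULT_Z_STEP = 3.0


@dataclass
class VoxelStack:
    """A named set of co-registered 3D intensity channels.

    Parameters
    ----------
    channels
        Mapping of channel name to a (nz, ny, nx) float array.  All channels
        must share one shape.
    voxel_size_xy, z_step
        Voxel geometry in micrometres.
    t_acquired
        Seconds since dye injection at which the stack was acquired.
    background_offset
        Detector background level (counts) added to every channel; recorded
        so background subtraction can be exact on synthetic data.
    stages
        Ordered provenance tags appended by each processing stage.
    """

    channels: dict[str, np.ndarray]
    voxel_size_xy: float = DEFAULT_VOXEL_XY
    z_step: float = DEFAULT_Z_STEP
    t_acquired: float = 10.0
    bit_depth: int = 16
    background_offset: float = 0.0
    stages: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("VoxelStack needs at least one channel")
        shapes = {ch: np.asarray(a).shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.voxel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("voxel sizes must be positive")
        self.channels = {
            ch: np.asarray(a, dtype=np.float64) for ch, a in self.channels.items()
        }

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    def with_channels(self, new: dict[str, np.ndarray], stage: str | None = None) -> "VoxelStack":
        """Copy of the stack with some channels replaced and a stage tag added."""
        channels = {**{k: v.copy() for k, v in self.channels.items()},
                    **{k: np.asarray(v, dtype=np.float64) for k, v in new.items()}}
        stages = self.stages + (stage,) if stage else self.stages
        return replace(self, channels=channels, stages=stages)

    def tagged(self, stage: str) -> "VoxelStack":
        return replace(self, channels=self.channels, stages=self.stages + (stage,))

    def copy(self) -> "VoxelStack":
        return replace(self, channels={k: v.copy() for k, v in self.channels.items()})
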