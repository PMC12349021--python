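"""Electrode montage: canonical DEAP channel order and the 8x9 scalp grid.

The 32 EEG channels of the DEAP cap (international 10-20 placement) are
embedded into an 8x9 matrix whose rows run front-to-back and whose columns
run left-to-right across the scalp.  Cells without an electrode are
structural zeros when features are mapped onto the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Channel order of the DEAP preprocessed arrays (EEG channels 0-31).
DEAP_CHANNELS: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
)

GRID_ROWS = 8
GRID_COLS = 9

# row -> [(channel, col), ...]; rows front-to-back, cols left-to-right
_DEFAULT_PLACEMENT: dict[str, tuple[int, int]] = {
    "Fp1": (0, 3), "Fp2": (0, 5),
    "AF3": (1, 3), "AF4": (1, 5),
    "F7": (2, 0), "F3": (2, 2), "Fz": (2, 4), "F4": (2, 6), "F8": (2, 8),
    "FC5": (3, 1), "FC1": (3, 3), "FC2": (3, 5), "FC6": (3, 7),
    "T7": (4, 0), "C3": (4, 2), "Cz": (4, 4), "C4": (4, 6), "T8": (4, 8),
    "CP5": (5, 1), "CP1": (5, 3), "CP2": (5, 5), "CP6": (5, 7),
    "P7": (6, 0), "P3": (6, 2), "Pz": (6, 4), "P4": (6, 6), "P8": (6, 8),
    "PO3": (7, 2), "O1": (7, 3), "Oz": (7, 4), "O2": (7, 5), "PO4": (7, 6),
}

#: Scalp regions used by the synthetic generator and the topographic maps.
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
                "FC5", "FC1", "FC2", "FC6"),
    "temporal": ("T7", "T8"),
    "central": ("C3", "Cz", "C4", "CP5", "CP1", "CP2", "CP6"),
    "parietal": ("P7", "P3", "Pz", "P4", "P8"),
    "occipital": ("PO3", "O1", "Oz", "O2", "PO4"),
}
#: Convenience alias: parietal + occipital electrodes.
POSTERIOR: tuple[str, ...] = REGIONS["parietal"] + REGIONS["occipital"]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Mapping from channel names to cells of the spatial grid."""

    placement: dict[str, tuple[int, int]]
    grid_rows: int = GRID_ROWS
    grid_cols: int = GRID_COLS
    channel_order: tuple[str, ...] = field(default=DEAP_CHANNELS)

    def __post_init__(self) -> None:
        if set(self.placement) != set(self.channel_order):
            missing = set(self.channel_order) - set(self.placement)
            extra = set(self.placement) - set(self.channel_order)
            raise ValueError(
                f"placement must cover the channel set exactly; "
                f"missing={sorted(missing)}, extra={sorted(extra)}"
            )
        cells = list(self.placement.values())
        if len(set(cells)) != len(cells):
            raise ValueError("placement cells must be distinct")
        for r, c in cells:
            if not (0 <= r < self.grid_rows and 0 <= c < self.grid_cols):
                raise ValueError(f"cell ({r}, {c}) outside the grid")

    @property
    def n_channels(self) -> int:
        return len(self.placement)

    def rows_cols(self, channel_names) -> tuple[list[int], list[int]]:
        """Grid coordinates for ``channel_names``, in that order."""
        rows = [self.placement[name][0] for name in channel_names]
        cols = [self.placement[name][1] for name in channel_names]
        return rows, cols


def default_layout() -> ElectrodeLayout:
    """The standard 8x9 arrangement of the 32 DEAP electrodes."""
    return ElectrodeLayout(placement=dict(_DEFAULT_PLACEMENT))


def load_layout(path) -> ElectrodeLayout:
    """Read a layout from a YAML/JSON file mapping channel -> [row, col]."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    placement = {str(k): (int(v[0]), int(v[1])) for k, v in raw.items()}
    return ElectrodeLayout(
        placement=placement, channel_order=tuple(placement),
    )


def region_of(channel: str) -> str:
    """Scalp region a channel belongs to."""
    for region, names in REGIONS.items():
        if channel in names:
            return region
    raise KeyError(f"unknown channel {channel!r}")
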