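"""Channel layouts and reduced montages.

The recording layout is the 64-channel actiCap arrangement of the extended
10-20 system (FCz is the reference and carries no data channel).  Two
families of reduced montages are provided:

* ``custom`` (32/21/16/8/4 channels): nested subsets centered on C1 and
  restricted to the left hemisphere and midline.  C1 overlies the motor
  cortex contralateral to the right arm, where the LRP preceding right-arm
  movements is maximal, so these montages carry the information that
  transfers from bilateral to unilateral movement planning.
* ``standard`` (32/21/16 channels): conventional whole-head constellations
  of the extended 10-20 system, used as a baseline.

The exact memberships are an editable configuration (YAML), not a contract:
invariants (nesting, laterality, C1 membership) are what the rest of the
package relies on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

# 64-channel actiCap layout, extended 10-20 names; FCz reference excluded.
CHANNELS_64 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    # second block of 32
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
)

REFERENCE = "FCz"

_CUSTOM_4 = ["C1", "C3", "FC1", "CP1"]
_CUSTOM_8 = _CUSTOM_4 + ["FC3", "CP3", "Cz", "C5"]
_CUSTOM_16 = _CUSTOM_8 + ["F1", "F3", "FC5", "CP5", "P1", "P3", "CPz", "Pz"]
_CUSTOM_21 = _CUSTOM_16 + ["F5", "FT7", "TP7", "P5", "Fz"]
_CUSTOM_32 = _CUSTOM_21 + ["Fp1", "AF3", "AF7", "F7", "T7", "FT9", "TP9",
                           "P7", "PO3", "POz", "Oz"]

_STANDARD_16 = ["Fp1", "Fp2", "F7", "F3", "F4", "F8", "T7", "C3", "C4", "T8",
                "P7", "P3", "P4", "P8", "O1", "O2"]
_STANDARD_21 = _STANDARD_16 + ["Fz", "Cz", "Pz", "Oz", "POz"]
_STANDARD_32 = list(CHANNELS_64[:32])

DEFAULT_MONTAGES: dict[tuple[str, int], list[str]] = {
    ("custom", 4): _CUSTOM_4,
    ("custom", 8): _CUSTOM_8,
    ("custom", 16): _CUSTOM_16,
    ("custom", 21): _CUSTOM_21,
    ("custom", 32): _CUSTOM_32,
    ("standard", 16): _STANDARD_16,
    ("standard", 21): _STANDARD_21,
    ("standard", 32): _STANDARD_32,
}


def _ten_twenty_index(name: str) -> int | None:
    """Numeric 10-20 index of a channel label, or None for midline (z)."""
    m = re.match(r"^[A-Za-z]+?(\d+)$", name)
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class Montage:
    """An ordered channel selection applied before feature extraction."""

    scheme: str
    n_channels: int
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.scheme not in ("custom", "standard"):
            raise ValueError(f"unknown montage scheme {self.scheme!r}")
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"montage lists {len(self.channel_names)} channels but "
                f"declares n_channels={self.n_channels}")
        if len(set(self.channel_names)) != self.n_channels:
            raise ValueError("montage channel names are not unique")
        unknown = [c for c in self.channel_names if c not in CHANNELS_64]
        if unknown:
            raise ValueError(f"channels not in the 64-channel layout: "
                             f"{unknown}")
        if self.scheme == "custom":
            if "C1" not in self.channel_names:
                raise ValueError("custom montages must contain C1")
            right = [c for c in self.channel_names
                     if (_ten_twenty_index(c) or 1) % 2 == 0]
            if right:
                raise ValueError(
                    f"custom montages must not contain right-hemisphere "
                    f"channels: {right}")

    @property
    def name(self) -> str:
        return f"{self.scheme}:{self.n_channels}"


def get_montage(scheme: str, n_channels: int,
                definitions: dict | None = None) -> Montage:
    """Return the configured montage for ``(scheme, n_channels)``.

    ``definitions`` may override the shipped channel lists (e.g. loaded via
    :func:`load_montage_definitions`).  Supported sizes are 32/21/16/8/4 for
    the custom scheme and 32/21/16 for the standard scheme.
    """
    table = DEFAULT_MONTAGES if definitions is None else definitions
    key = (scheme, n_channels)
    if key not in table:
        supported = sorted(set(table), key=str)
        raise ValueError(
            f"unsupported montage ({scheme}, {n_channels}); "
            f"supported: {supported}")
    return Montage(scheme=scheme, n_channels=n_channels,
                   channel_names=tuple(table[key]))


def parse_montage_spec(spec: str) -> Montage:
    """Parse a ``scheme:n`` string such as ``custom:8``."""
    try:
        scheme, n = spec.split(":")
        return get_montage(scheme, int(n))
    except ValueError as e:
        raise ValueError(f"invalid montage spec {spec!r}: {e}") from e


def load_montage_definitions(path) -> dict[tuple[str, int], list[str]]:
    """Load montage definitions from a YAML file.

    Layout: ``{scheme: {n_channels: [names...]}}``.
    """
    with open(path) as f:
        raw = yaml.safe_load(f)
    table = {}
    for scheme, sizes in raw.items():
        for n, names in sizes.items():
            table[(str(scheme), int(n))] = list(names)
    return table


def apply_montage(recording, montage: Montage):
    """Restrict a recording to the montage channels, in montage order."""
    missing = [c for c in montage.channel_names
               if c not in recording.channel_names]
    if missing:
        raise ValueError(f"recording is missing montage channels: {missing}")
    idx = [recording.channel_names.index(c) for c in montage.channel_names]
    return recording.select_channels(idx)
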