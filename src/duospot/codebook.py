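"""Dual-color combinatorial codebook: channels, marker codes, and validity rules.

Each marker is identified by an unordered pair of signal channels (a *color
code*).  Six signal channels yield ``C(6, 2) = 15`` possible codes; restricting
one channel to a single partner (used here for TexasRed, which suffers
bleed-through from Cy5) reduces the panel to 11 usable codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import yaml

__all__ = [
    "NUCLEAR_CHANNEL",
    "SIGNAL_CHANNELS",
    "Channel",
    "ColorCode",
    "MarkerDef",
    "Codebook",
    "enumerate_codes",
    "restrict_channel",
    "build_default_panel",
    "validate_codebook",
]

#: Canonical channel names.  Config files may alias these, but every internal
#: join uses the canonical spelling.
NUCLEAR_CHANNEL = "DAPI"
SIGNAL_CHANNELS = ("Atto425", "Atto488", "Cy3", "TexasRed", "Cy5", "AF750")


@dataclass(frozen=True)
class Channel:
    """A microscope channel, either a signal channel or the nuclear stain."""

    name: str
    role: str = "signal"  # "signal" | "nuclear"

    def __post_init__(self) -> None:
        if self.role not in ("signal", "nuclear"):
            raise ValueError(f"unknown channel role {self.role!r}")


def _as_code(pair: Iterable[str]) -> tuple[str, str]:
    """Normalize a channel pair to a sorted 2-tuple (order-insensitive)."""
    members = tuple(sorted(pair))
    if len(members) != 2 or members[0] == members[1]:
        raise ValueError(f"a color code must contain exactly 2 distinct channels, got {pair!r}")
    return members


@dataclass(frozen=True)
class ColorCode:
    """An unordered pair of distinct signal channels identifying one marker."""

    pair: tuple[str, str]

    def __init__(self, pair: Iterable[str]):
        object.__setattr__(self, "pair", _as_code(pair))

    def __contains__(self, channel: str) -> bool:
        return channel in self.pair

    def __iter__(self):
        return iter(self.pair)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ColorCode({self.pair[0]}+{self.pair[1]})"


@dataclass(frozen=True)
class MarkerDef:
    """A marker: one or more pooled genes reported under one color code."""

    name: str
    genes: tuple[str, ...]
    code: ColorCode

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker {self.name!r} has no genes")


@dataclass
class Codebook:
    """Channel set, marker panel, and channel-pairing restrictions."""

    channels: tuple[Channel, ...]
    markers: tuple[MarkerDef, ...]
    restrictions: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    @property
    def signal_channels(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels if c.role == "signal")

    @property
    def nuclear_channel(self) -> str:
        nuclear = [c.name for c in self.channels if c.role == "nuclear"]
        if len(nuclear) != 1:
            raise ValueError("codebook must define exactly one nuclear channel")
        return nuclear[0]

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.markers)

    def marker(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def code_to_marker(self) -> dict[tuple[str, str], str]:
        return {m.code.pair: m.name for m in self.markers}

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "channels": [{"name": c.name, "role": c.role} for c in self.channels],
            "markers": [
                {"name": m.name, "genes": list(m.genes), "code": list(m.code.pair)}
                for m in self.markers
            ],
            "restrictions": [list(r) for r in self.restrictions],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Codebook":
        channels = tuple(Channel(c["name"], c.get("role", "signal")) for c in data["channels"])
        markers = tuple(
            MarkerDef(m["name"], tuple(m["genes"]), ColorCode(m["code"]))
            for m in data["markers"]
        )
        restrictions = tuple(tuple(r) for r in data.get("restrictions", ()))
        return cls(channels=channels, markers=markers, restrictions=restrictions)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def enumerate_codes(channels: Iterable[str], k: int = 2) -> set[tuple[str, ...]]:
    """Enumerate all size-``k`` channel subsets available as color codes.

    Returns the full set of unordered combinations; ``|result| = C(n, k)``.
    """
    names = tuple(dict.fromkeys(channels))
    if k < 1 or k > len(names):
        raise ValueError(f"code size k={k} out of range for {len(names)} channels")
    return {tuple(sorted(c)) for c in combinations(names, k)}


def restrict_channel(
    codes: Iterable[tuple[str, ...]], channel: str, partner: str
) -> set[tuple[str, ...]]:
    """Drop every code containing ``channel`` except ``{channel, partner}``.

    Used to reserve a bleed-through-prone channel for a single pairing.
    """
    if channel == partner:
        raise ValueError("restriction partner must differ from the restricted channel")
    allowed = tuple(sorted((channel, partner)))
    return {c for c in codes if channel not in c or tuple(sorted(c)) == allowed}


#: Marker panel: name -> (genes, code pair).
_DEFAULT_PANEL: tuple[tuple[str, tuple[str, ...], tuple[str, str]], ...] = (
    ("hem", ("PTPRC", "ITGAM", "FCGR3A", "FCGR3B", "CD4", "ITGB2"), ("TexasRed", "Cy3")),
    ("VIM", ("VIM",), ("Atto488", "Cy3")),
    ("KRT", ("KRT8", "KRT18", "KRT19"), ("Atto425", "Cy5")),
    ("EPCAM", ("EPCAM",), ("Atto488", "AF750")),
    ("PSA", ("KLK3",), ("Atto425", "AF750")),
    ("PSMA", ("FOLH1",), ("Cy3", "Cy5")),
    ("AR-FL", ("AR-FL",), ("Atto488", "Cy5")),
    ("AR-V7", ("AR-V7",), ("Cy3", "AF750")),
    ("NE", ("SYP", "CHGA", "NCAM1"), ("Cy5", "AF750")),
    ("SLFN11", ("SLFN11",), ("Atto425", "Atto488")),
    ("DLL3", ("DLL3",), ("Atto425", "Cy3")),
)


def build_default_panel() -> Codebook:
    """Build the default 11-marker panel with the TexasRed->Cy3 restriction."""
    channels = (Channel(NUCLEAR_CHANNEL, "nuclear"),) + tuple(
        Channel(name) for name in SIGNAL_CHANNELS
    )
    markers = tuple(
        MarkerDef(name, genes, ColorCode(code)) for name, genes, code in _DEFAULT_PANEL
    )
    return Codebook(channels=channels, markers=markers, restrictions=(("TexasRed", "Cy3"),))


def validate_codebook(cb: Codebook) -> list[str]:
    """Return a list of violation descriptions (empty means valid)."""
    violations: list[str] = []

    nuclear = [c for c in cb.channels if c.role == "nuclear"]
    if len(nuclear) != 1:
        violations.append(f"expected exactly 1 nuclear channel, found {len(nuclear)}")
    signal_names = [c.name for c in cb.channels if c.role == "signal"]
    if len(signal_names) != len(set(signal_names)):
        violations.append("duplicate signal channel names")
    known = set(signal_names)

    seen: dict[tuple[str, str], str] = {}
    for m in cb.markers:
        if m.code.pair in seen:
            violations.append(
                f"markers {seen[m.code.pair]!r} and {m.name!r} share code {m.code.pair}"
            )
        else:
            seen[m.code.pair] = m.name
        for ch in m.code:
            if ch not in known:
                violations.append(f"marker {m.name!r} uses unknown channel {ch!r}")

    for channel, partner in cb.restrictions:
        allowed = tuple(sorted((channel, partner)))
        for m in cb.markers:
            if channel in m.code and m.code.pair != allowed:
                violations.append(
                    f"marker {m.name!r} code {m.code.pair} violates restriction "
                    f"{channel}->{partner}"
                )
    return violations
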