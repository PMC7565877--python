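"""Macro-region definitions and their adjacency graph.

A macro-region is a named residue patch on a ligand diffusion pathway.
Entry regions are reachable directly from solvent, infiltration regions
only through entry regions, and external regions sit outside the channel
mouths but bridge entry regions.  The package ships a default MR1-MR20
topology (classes, channel memberships, adjacency) with residue lists left
as user-supplied placeholders.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .structures import ResidueSelection

__all__ = ["MacroRegion", "RegionGraph", "load_region_graph", "default_region_graph"]

SOLVENT = "solvent"
CHANNELS = ("CH2", "CH3A", "CH3B", "CH3C", "CH3D")
#: Regions counting as a completed infiltration terminus.
TERMINAL_REGIONS = frozenset({"MR19", "MR20"})

_CLASS_RANK = {"external": 0, "entry": 1, "infiltration": 2}


@dataclass
class MacroRegion:
    name: str
    region_class: str                      # entry | infiltration | external
    selection: ResidueSelection | None = None
    channel_memberships: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.region_class not in _CLASS_RANK:
            raise ConfigError(
                f"{self.name}: unknown region class {self.region_class!r}")
        bad = set(self.channel_memberships) - set(CHANNELS)
        if bad:
            raise ConfigError(f"{self.name}: unknown channel(s) {sorted(bad)}")
        self.channel_memberships = frozenset(self.channel_memberships)

    def depth_rank(self) -> int:
        """external < entry < infiltration < terminus (MR19/MR20)."""
        if self.name in TERMINAL_REGIONS:
            return 3
        return _CLASS_RANK[self.region_class]


@dataclass
class RegionGraph:
    regions: list[MacroRegion]
    adjacency: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ConfigError("region names must be unique")
        self._by_name = {r.name: r for r in self.regions}
        known = set(names) | {SOLVENT}
        for pair in self.adjacency:
            if not pair <= known:
                raise ConfigError(f"adjacency references unknown region: {set(pair)}")
        for ch in {c for r in self.regions for c in r.channel_memberships}:
            if not self.channel_members(ch):
                raise ConfigError(f"channel {ch} has no member regions")

    def __getitem__(self, name: str) -> MacroRegion:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def channel_members(self, channel: str) -> list[str]:
        return [r.name for r in self.regions if channel in r.channel_memberships]

    def channels(self) -> list[str]:
        present = {c for r in self.regions for c in r.channel_memberships}
        return [c for c in CHANNELS if c in present]

    def adjacent(self, a: str, b: str) -> bool:
        """Adjacency test; solvent is implicitly adjacent to non-infiltration regions."""
        if frozenset((a, b)) in self.adjacency:
            return True
        for x, y in ((a, b), (b, a)):
            if x == SOLVENT and y in self._by_name:
                return self._by_name[y].region_class in ("entry", "external")
        return False

    def depth_rank(self, name: str) -> int:
        if name == SOLVENT:
            return -1
        return self._by_name[name].depth_rank()

    def with_selections(self, selections: dict[str, ResidueSelection]) -> "RegionGraph":
        """Copy of the graph with residue selections filled in."""
        regions = []
        for r in self.regions:
            regions.append(MacroRegion(
                name=r.name,
                region_class=r.region_class,
                selection=selections.get(r.name, r.selection),
                channel_memberships=r.channel_memberships,
            ))
        return RegionGraph(regions=regions, adjacency=set(self.adjacency))


def _parse_selection(raw) -> ResidueSelection | None:
    if not raw:
        return None
    mapping: dict[str, set[int]] = {}
    for sub, residues in raw.items():
        acc: set[int] = set()
        for item in residues:
            if isinstance(item, str) and "-" in item:
                lo, hi = item.split("-")
                acc.update(range(int(lo), int(hi) + 1))
            else:
                acc.add(int(item))
        mapping[str(sub)] = acc
    return ResidueSelection.from_dict(mapping)


def load_region_graph(path_or_stream) -> RegionGraph:
    """Load a region map from a YAML file or stream.

    Format::

        regions:
          MR1: {class: entry, channels: [CH2], residues: {RPB1: [770-780]}}
          ...
        adjacency:
          - [MR1, MR2]
    """
    if hasattr(path_or_stream, "read"):
        doc = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "regions" not in doc:
        raise ConfigError("region map must contain a 'regions' mapping")
    regions = []
    for name, body in doc["regions"].items():
        body = body or {}
        regions.append(MacroRegion(
            name=str(name),
            region_class=str(body.get("class", "entry")),
            selection=_parse_selection(body.get("residues")),
            channel_memberships=frozenset(body.get("channels", []) or []),
        ))
    adjacency = {frozenset(map(str, pair)) for pair in doc.get("adjacency", [])}
    return RegionGraph(regions=regions, adjacency=adjacency)


def default_region_graph() -> RegionGraph:
    """The bundled MR1-MR20 topology (residue lists are placeholders)."""
    ref = importlib.resources.files("ntpflow.data").joinpath("mr_map.yaml")
    with ref.open() as fh:
        return load_region_graph(fh)
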