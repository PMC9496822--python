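"""Brain-region analysis of detected communities.

Maps the 32-channel 10-20 electrode montage onto five anatomical regions
(frontal, temporal, parietal, occipital, central) and computes region-level
summaries of a community division: the largest modules, the fraction of
each region's electrodes they occupy, shared nodes between two divisions,
and inter-module edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InvalidInputError, InvalidParameterError
from .network import BinaryNetwork, Partition

__all__ = [
    "ElectrodeMap",
    "RegionReport",
    "default_electrode_map",
    "top_k_modules",
    "region_proportions",
    "common_nodes",
    "intermodule_edge_count",
]

REGIONS = ("Frontal", "Temporal", "Parietal", "Occipital", "Central")

_REGION_MEMBERS: dict[str, tuple[str, ...]] = {
    "Frontal": ("Fp1", "Fp2", "F3", "F4", "Fz", "AF3", "AF4"),
    "Temporal": ("F7", "T7", "P7", "FC5", "CP5", "F8", "T8", "P8", "FC6", "CP6"),
    "Parietal": ("P3", "P4", "Pz"),
    "Occipital": ("O1", "O2", "Oz", "PO3", "PO4"),
    "Central": ("C3", "C4", "Cz", "CP1", "CP2", "FC1", "FC2"),
}


@dataclass(frozen=True)
class ElectrodeMap:
    """Region assignment of the 32-electrode montage.

    Electrode names are matched case-insensitively (sources print both
    "FP1" and "Fp1") and stored with canonical capitalization.
    """

    region_members: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        members = {r: tuple(v) for r, v in self.region_members.items()}
        object.__setattr__(self, "region_members", members)
        all_named = [e for v in members.values() for e in v]
        if len(all_named) != 32 or len({e.lower() for e in all_named}) != 32:
            raise InvalidInputError("regions must partition exactly 32 electrodes")
        lookup = {}
        for region, electrodes in members.items():
            for e in electrodes:
                lookup[e.lower()] = (region, e)
        object.__setattr__(self, "_lookup", lookup)

    def region_of(self, electrode: str) -> str:
        try:
            return self.__dict__["_lookup"][electrode.lower()][0]
        except KeyError:
            raise InvalidInputError(f"unknown electrode name: {electrode!r}") from None

    def canonical(self, electrode: str) -> str:
        try:
            return self.__dict__["_lookup"][electrode.lower()][1]
        except KeyError:
            raise InvalidInputError(f"unknown electrode name: {electrode!r}") from None


def default_electrode_map() -> ElectrodeMap:
    """The standard 32-channel region grouping (7/10/3/5/7 electrodes)."""
    return ElectrodeMap(region_members=_REGION_MEMBERS)


@dataclass(frozen=True)
class RegionReport:
    """Per-region electrode presence and percentage of the region covered."""

    present_nodes: Mapping[str, tuple[str, ...]]
    proportion_pct: Mapping[str, float]  # rounded to one decimal


def top_k_modules(
    partition: Partition, k: int, node_names: Sequence[str] | None = None
) -> list[tuple[str, ...]]:
    """The k largest communities by node count, descending.

    Size ties are broken by the smallest member name; if the partition has
    fewer than k communities all are returned.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    names = (
        tuple(node_names)
        if node_names is not None
        else tuple(str(i) for i in range(partition.n_nodes))
    )
    modules = [tuple(names[i] for i in sorted(g)) for g in partition.groups]
    modules.sort(key=lambda mod: (-len(mod), min(mod)))
    return modules[: min(k, len(modules))]


def region_proportions(
    node_list: Iterable[str], emap: ElectrodeMap | None = None
) -> RegionReport:
    """Fraction of each region's electrodes present in ``node_list``.

    Reported as a percentage rounded to one decimal (e.g. 6 of the 7
    frontal electrodes -> 85.7).
    """
    emap = emap or default_electrode_map()
    canon = {emap.canonical(name) for name in node_list}
    present: dict[str, tuple[str, ...]] = {}
    pct: dict[str, float] = {}
    for region in REGIONS:
        members = emap.region_members[region]
        hits = tuple(e for e in members if e in canon)
        present[region] = hits
        pct[region] = round(100.0 * len(hits) / len(members), 1)
    return RegionReport(present_nodes=present, proportion_pct=pct)


def common_nodes(
    modules_a: Iterable[Iterable[str]],
    modules_b: Iterable[Iterable[str]],
    emap: ElectrodeMap | None = None,
) -> list[str]:
    """Sorted intersection of the two sides' module unions (canonical names)."""
    emap = emap or default_electrode_map()
    union_a = {emap.canonical(e) for mod in modules_a for e in mod}
    union_b = {emap.canonical(e) for mod in modules_b for e in mod}
    return sorted(union_a & union_b)


def intermodule_edge_count(network: BinaryNetwork, partition: Partition) -> int:
    """Number of edges whose endpoints lie in different communities."""
    if partition.n_nodes != network.n_nodes:
        raise InvalidInputError("partition does not cover the network")
    labels = partition.labels()
    return sum(1 for u, v in network.edges if labels[u] != labels[v])
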