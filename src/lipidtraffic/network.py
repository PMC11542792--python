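"""Compartment networks: the tissues/fluids of the system and which pairs exchange lipids.

The traffic analysis is network-generic: any set of named compartments with
undirected "metabolically adjacent" edges will do.  Two mouse networks ship
as editable YAML configs:

``mouse_default``
    plasma connected to every tissue (the circulation as hub) plus the
    small intestine-liver portal edge.
``mouse_adipose_linked``
    the default plus direct edges between the three adipose depots
    (BAT-iWAT, BAT-eWAT, iWAT-eWAT), for sensitivity analysis of the
    B/N2 split when adipose tissues are treated as exchanging lipids
    directly.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import yaml

__all__ = [
    "CompartmentNetwork",
    "NetworkConfigError",
    "NetworkWarning",
    "load_network",
    "default_network",
    "are_adjacent",
]


class NetworkConfigError(ValueError):
    """Invalid network definition (unknown compartment, self-loop, empty set ...)."""


class NetworkWarning(UserWarning):
    """Soft issues: disconnected graph, duplicate edges collapsed."""


@dataclass(frozen=True)
class CompartmentNetwork:
    """Named compartments plus undirected adjacency edges.

    Construct through :meth:`from_parts`, :meth:`from_dict` or
    :func:`load_network`, which validate and canonicalise the definition.
    """

    compartments: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    name: str = "unnamed"

    @classmethod
    def from_parts(
        cls,
        compartments: Iterable[str],
        edges: Iterable[tuple[str, str]],
        name: str = "unnamed",
    ) -> "CompartmentNetwork":
        comps = tuple(dict.fromkeys(str(c) for c in compartments))
        if not comps:
            raise NetworkConfigError("network has an empty compartment list")
        known = set(comps)
        seen: set[frozenset[str]] = set()
        n_dup = 0
        for a, b in edges:
            a, b = str(a), str(b)
            for node in (a, b):
                if node not in known:
                    raise NetworkConfigError(
                        f"edge ({a!r}, {b!r}) references unknown compartment {node!r}"
                    )
            if a == b:
                raise NetworkConfigError(f"self-loop on compartment {a!r}")
            e = frozenset((a, b))
            if e in seen:
                n_dup += 1
            seen.add(e)
        if n_dup:
            warnings.warn(f"collapsed {n_dup} duplicate edge(s)", NetworkWarning, stacklevel=3)
        net = cls(compartments=comps, edges=frozenset(seen), name=name)
        if len(comps) > 1 and not net.is_connected:
            warnings.warn(
                f"network {name!r} is not connected", NetworkWarning, stacklevel=3
            )
        return net

    @classmethod
    def from_dict(cls, cfg: Mapping, name: str = "unnamed") -> "CompartmentNetwork":
        if "compartments" not in cfg:
            raise NetworkConfigError("network config missing 'compartments'")
        edges = [tuple(e) for e in cfg.get("edges", [])]
        for e in edges:
            if len(e) != 2:
                raise NetworkConfigError(f"edge {e!r} is not a pair")
        return cls.from_parts(cfg["compartments"], edges, name=cfg.get("name", name))

    # -- graph views ------------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.compartments)
        g.add_edges_from(tuple(sorted(e)) for e in self.edges)
        return g

    @property
    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def neighbors(self, compartment: str) -> tuple[str, ...]:
        self._check_known(compartment)
        return tuple(sorted(n for e in self.edges if compartment in e for n in e if n != compartment))

    def _check_known(self, compartment: str) -> None:
        if compartment not in self.compartments:
            raise NetworkConfigError(f"unknown compartment {compartment!r}")

    def are_adjacent(self, a: str, b: str) -> bool:
        """True iff {a, b} is an edge.  Symmetric; errors on unknown names or a == b."""
        self._check_known(a)
        self._check_known(b)
        if a == b:
            raise NetworkConfigError(f"adjacency of {a!r} with itself is not defined")
        return frozenset((a, b)) in self.edges

    def has_any_adjacent_pair(self, compartments: Iterable[str]) -> bool:
        """True iff some pair among ``compartments`` is an edge."""
        comps = sorted(set(compartments))
        return any(frozenset(p) in self.edges for p in combinations(comps, 2))

    def non_adjacent_pairs(self) -> list[tuple[str, str]]:
        return [
            p
            for p in combinations(sorted(self.compartments), 2)
            if frozenset(p) not in self.edges
        ]

    # -- provenance -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "compartments": list(self.compartments),
            "edges": sorted(sorted(e) for e in self.edges),
        }

    @property
    def hash_hex(self) -> str:
        """Stable digest of the canonical definition, recorded in every run's metadata."""
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_network(path: str | Path) -> CompartmentNetwork:
    """Load and validate a network from a YAML config file."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, Mapping):
        raise NetworkConfigError(f"{path}: network config must be a mapping")
    return CompartmentNetwork.from_dict(cfg, name=path.stem)


def default_network(variant: str = "default") -> CompartmentNetwork:
    """The shipped mouse network; ``variant`` is ``"default"`` or ``"adipose_linked"``."""
    fname = {"default": "mouse_default.yaml", "adipose_linked": "mouse_adipose_linked.yaml"}
    if variant not in fname:
        raise ValueError(f"unknown network variant {variant!r}; choose from {sorted(fname)}")
    ref = resources.files("lipidtraffic.data") / fname[variant]
    cfg = yaml.safe_load(ref.read_text())
    return CompartmentNetwork.from_dict(cfg)


def are_adjacent(net: CompartmentNetwork, a: str, b: str) -> bool:
    """Functional wrapper for :meth:`CompartmentNetwork.are_adjacent`."""
    return net.are_adjacent(a, b)
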