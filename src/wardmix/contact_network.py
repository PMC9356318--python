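"""Daily unit rosters, pairwise colocation contacts, and contact networks.

Two admissions recorded in the same hospital unit on the same calendar day
are counted as one contact for that day; a unit-day cell holding k patients
contributes k-choose-2 pairwise contacts.  Repeated contacts on later days
add linearly, so the edge weight between two admissions is their number of
shared unit-days.  Each admission is its own node even when two admissions
belong to the same patient, and networks never cross hospitals.

A patient present in two units on the same day (a transfer boundary day,
or overlapping stays) sits on both rosters; a pair co-located in two units
the same day therefore yields two contact events by default.  Pass
``dedupe_same_day=True`` to collapse those to one event per pair per day.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, NamedTuple

import networkx as nx

from wardmix.encounter_model import EncounterBundle, UnitStay

Window = tuple[date, date]


class ContactEvent(NamedTuple):
    """One pairwise contact: the pair is canonically ordered (a < b)."""

    admission_a: str
    admission_b: str
    unit_id: str
    date: date


@dataclass
class ContactNetwork:
    """Undirected weighted contact graph over admissions in a window.

    Edge weight = number of shared (unit, day) cells, i.e. contact-days.
    Isolated nodes (admissions with roster days but no co-located partner)
    are retained.
    """

    graph: nx.Graph
    hospital_id: str
    window: Window
    unit_types: dict[str, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weights(self) -> dict[tuple[str, str], int]:
        return {
            (min(a, b), max(a, b)): d["weight"]
            for a, b, d in self.graph.edges(data=True)
        }


def daily_rosters(
    stays: Iterable[UnitStay], window: Window
) -> dict[tuple[str, date], set[str]]:
    """Map each (unit_id, day) cell to the set of admissions present.

    Stay intervals are inclusive on both ends and clipped to the window;
    cells with no members are omitted.
    """
    start, end = window
    if start > end:
        raise ValueError("empty window")
    rosters: dict[tuple[str, date], set[str]] = {}
    for s in stays:
        d = max(s.entry_date, start)
        last = min(s.exit_date, end)
        while d <= last:
            rosters.setdefault((s.unit_id, d), set()).add(s.admission_id)
            d += timedelta(days=1)
    return rosters


def enumerate_contacts(
    rosters: dict[tuple[str, date], set[str]],
    dedupe_same_day: bool = False,
) -> list[ContactEvent]:
    """Enumerate all pairwise contacts: each k-member cell yields kC2 events.

    Events are returned in deterministic order (unit, day, pair).  With
    ``dedupe_same_day`` a pair co-located in several units on one day is
    counted once (attributed to the lexicographically first unit).
    """
    events: list[ContactEvent] = []
    for (unit_id, day) in sorted(rosters):
        members = sorted(rosters[(unit_id, day)])
        for a, b in itertools.combinations(members, 2):
            events.append(ContactEvent(a, b, unit_id, day))
    if dedupe_same_day:
        best: dict[tuple[str, str, date], ContactEvent] = {}
        for ev in events:
            key = (ev.admission_a, ev.admission_b, ev.date)
            if key not in best or ev.unit_id < best[key].unit_id:
                best[key] = ev
        events = sorted(best.values())
    return events


def build_network(
    bundle: EncounterBundle,
    hospital_id: str,
    window: Window,
    dedupe_same_day: bool = False,
) -> ContactNetwork:
    """Assemble the per-hospital contact network for a time window.

    Nodes are all admissions of that hospital with at least one roster day
    inside the window (isolates included); edge weight(a, b) counts the
    (unit, day) cells containing both.
    """
    if hospital_id not in bundle.hospital_ids():
        raise KeyError(
            f"hospital {hospital_id!r} not in bundle; "
            f"available: {bundle.hospital_ids()}"
        )
    stays = bundle.stays_for_hospital(hospital_id)
    rosters = daily_rosters(stays, window)
    events = enumerate_contacts(rosters, dedupe_same_day=dedupe_same_day)

    g = nx.Graph()
    active = set()
    for members in rosters.values():
        active |= members
    g.add_nodes_from(sorted(active))
    for ev in events:
        if g.has_edge(ev.admission_a, ev.admission_b):
            g[ev.admission_a][ev.admission_b]["weight"] += 1
        else:
            g.add_edge(ev.admission_a, ev.admission_b, weight=1)
    unit_types = {s.unit_id: s.unit_type for s in stays}
    return ContactNetwork(
        graph=g, hospital_id=hospital_id, window=window, unit_types=unit_types
    )


def multiward_summary(
    network: ContactNetwork, stays: Iterable[UnitStay]
) -> dict[str, float | bool]:
    """Share of multi-unit admissions and of edges touching one.

    An admission is multi-unit when its stays span >= 2 distinct unit ids.
    Returns percentages in [0, 100]; a zero-edge network reports the edge
    percentage as 0 with ``zero_edges=True``.
    """
    units_per_adm: dict[str, set[str]] = {}
    for s in stays:
        units_per_adm.setdefault(s.admission_id, set()).add(s.unit_id)
    nodes = list(network.graph.nodes)
    multi = {a for a in nodes if len(units_per_adm.get(a, set())) >= 2}
    n_nodes = len(nodes)
    pct_adm = 100.0 * len(multi) / n_nodes if n_nodes else 0.0
    n_edges = network.n_edges
    if n_edges == 0:
        return {
            "pct_multiunit_admissions": pct_adm,
            "pct_edges_touching_multiunit": 0.0,
            "zero_edges": True,
        }
    touching = sum(
        1 for a, b in network.graph.edges if a in multi or b in multi
    )
    return {
        "pct_multiunit_admissions": pct_adm,
        "pct_edges_touching_multiunit": 100.0 * touching / n_edges,
        "zero_edges": False,
    }


def export_edge_list(network: ContactNetwork, path) -> None:
    """Write the weighted edge list as CSV (admission_a,admission_b,weight)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["admission_a", "admission_b", "weight"])
        for (a, b), wt in sorted(network.edge_weights().items()):
            w.writerow([a, b, wt])
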