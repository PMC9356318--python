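"""Shared fixtures: hand-built encounter bundles and brute-force oracles."""

from __future__ import annotations

from datetime import date, timedelta

import pytest

from wardmix.encounter_model import (
    AbxExposure,
    Admission,
    EncounterBundle,
    UnitStay,
)

JAN1 = date(2017, 1, 1)


def d(day: int) -> date:
    """Day *day* of January 2017 (d(1) = 2017-01-01)."""
    return JAN1 + timedelta(days=day - 1)


def mk_adm(aid, age=50, elix=0, hospital="H1", sex="F",
           admit=d(1), discharge=d(31), patient=None) -> Admission:
    return Admission(
        admission_id=aid,
        patient_id=patient or f"P-{aid}",
        hospital_id=hospital,
        age=age,
        sex=sex,
        elixhauser=elix,
        admit_date=admit,
        discharge_date=discharge,
    )


def mk_stay(aid, unit="U1", entry=d(1), exit=d(3), unit_type="adult medical ward") -> UnitStay:
    return UnitStay(admission_id=aid, unit_id=unit, unit_type=unit_type,
                    entry_date=entry, exit_date=exit)


def mk_exp(aid, day, rank="narrow") -> AbxExposure:
    return AbxExposure(admission_id=aid, date=day, rank=rank)


def brute_force_edge_weights(stays, window):
    """All-pairs/all-days/all-units oracle for contact-network edge weights.

    Independently of the roster machinery: expand each stay into its set of
    in-window (unit, day) presences straight from the interval endpoints,
    then for every unordered admission pair and every unit count the days
    both were present.
    """
    start, end = window
    presence: dict[str, dict[str, set[date]]] = {}
    for s in stays:
        day = max(s.entry_date, start)
        while day <= min(s.exit_date, end):
            presence.setdefault(s.admission_id, {}).setdefault(s.unit_id, set()).add(day)
            day += timedelta(days=1)
    admissions = sorted(presence)
    units = sorted({s.unit_id for s in stays})
    weights = {}
    for i, a in enumerate(admissions):
        for b in admissions[i + 1:]:
            w = 0
            for u in units:
                w += len(presence[a].get(u, set()) & presence[b].get(u, set()))
            if w:
                weights[(a, b)] = w
    return weights


def bfs_centralities(adjacency: dict):
    """Brute-force betweenness (unnormalized) and closeness via explicit
    BFS and shortest-path enumeration; independent of networkx."""
    nodes = sorted(adjacency)

    def bfs_dist(src):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for v in frontier:
                for w in adjacency[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
            frontier = nxt
        return dist

    def all_shortest_paths(src, dst, dist):
        # walk backwards from dst along strictly decreasing distance
        paths = []

        def back(v, acc):
            if v == src:
                paths.append([src] + acc)
                return
            for w in adjacency[v]:
                if w in dist and dist[w] == dist[v] - 1:
                    back(w, [v] + acc)

        if dst in dist:
            back(dst, [])
        return paths

    betweenness = {v: 0.0 for v in nodes}
    closeness = {}
    for s in nodes:
        dist = bfs_dist(s)
        reach = [v for v in dist if v != s]
        if reach:
            closeness[s] = len(reach) / sum(dist[v] for v in reach)
            # networkx scales by reachable fraction; on a connected
            # component that factor is (n_reach)/(n_comp-1) = 1
        else:
            closeness[s] = 0.0
        for t in nodes:
            if t <= s or t not in dist:
                continue
            paths = all_shortest_paths(s, t, dist)
            for p in paths:
                for interior in p[1:-1]:
                    betweenness[interior] += 1.0 / len(paths)
    return betweenness, closeness


@pytest.fixture
def tiny_bundle() -> EncounterBundle:
    """3 admissions, 4 stays, 2 exposures; A and B overlap in U1 on Jan 2-3."""
    return EncounterBundle(
        admissions=[
            mk_adm("A", age=30, elix=2, admit=d(1), discharge=d(5)),
            mk_adm("B", age=40, elix=4, admit=d(2), discharge=d(6)),
            mk_adm("C", age=90, elix=0, admit=d(1), discharge=d(10)),
        ],
        stays=[
            mk_stay("A", unit="U1", entry=d(1), exit=d(3)),
            mk_stay("A", unit="U2", entry=d(3), exit=d(5)),
            mk_stay("B", unit="U1", entry=d(2), exit=d(6)),
            mk_stay("C", unit="U3", entry=d(1), exit=d(10)),
        ],
        exposures=[
            mk_exp("A", d(2), "narrow"),
            mk_exp("B", d(2), "extended"),
        ],
    )
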