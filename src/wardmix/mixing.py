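"""Mixing matrices by age, Elixhauser score, and antibiotic spectrum rank.

A mixing matrix records, for every contact event (two admissions sharing a
unit on a calendar day), the classes of the two participants.  Because
contacts accrue per day, groups with long lengths of stay contribute
disproportionately: the matrix weights the class distribution by exposure
time, not by headcount.

Counting convention: each unordered contact between classes i and j adds 1
to cell (i, j) AND 1 to cell (j, i); a same-class contact adds 2 to the
diagonal.  This ordered-pair (symmetric double-count) convention makes
every matrix symmetric by construction and makes row i's sum equal the
total contact exposure of class-i patients.

Axes:

* age — 91 single-year classes, 0..90 (ages top-coded at 90);
* elixhauser — 17 classes, scores 0..16;
* abx — the 4 spectrum ranks (narrow, broad, extended, protected); an
  admission's class on a given day is the SET of ranks it is exposed to,
  and a contact contributes the full cross-product of the two sets.
  Contacts where either side has no active rank are excluded from the 4x4
  matrix and tallied separately (see :func:`abx_none_ratio`).

Normalization is cellwise min-max over the whole matrix:
``(x - min) / (max - min)``, mapping the least-mixed cell to 0 and the
most-mixed to 1; a constant matrix normalizes to all zeros with a
degeneracy flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from wardmix.contact_network import (
    ContactEvent,
    daily_rosters,
    enumerate_contacts,
)
from wardmix.encounter_model import ABX_RANKS, AGE_MAX, ELIX_MAX, EncounterBundle

AGE_LABELS = tuple(range(AGE_MAX + 1))
ELIX_LABELS = tuple(range(ELIX_MAX + 1))

ClassOf = Callable[[str, date], object]


@dataclass(frozen=True)
class Scope:
    """Restriction of an analysis to one hospital, window, and unit subset."""

    hospital_id: str
    window: tuple[date, date]
    unit_ids: frozenset[str] | None = None
    unit_types: frozenset[str] | None = None

    def admits_unit(self, unit_id: str, unit_type: str) -> bool:
        if self.unit_ids is not None and unit_id not in self.unit_ids:
            return False
        if self.unit_types is not None and unit_type not in self.unit_types:
            return False
        return True


@dataclass
class MixingMatrix:
    axis: str  # "age" | "elixhauser" | "abx"
    labels: tuple
    counts: np.ndarray  # square, nonnegative int, symmetric
    scope: Scope | None = None
    normalized: np.ndarray | None = None
    degenerate_norm: bool = False
    n_excluded: int = 0  # events dropped for unclassifiable participants

    def __post_init__(self):
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts shape does not match labels")

    def index_of(self, label) -> int:
        return self.labels.index(label)

    def cell(self, i_label, j_label, normalized: bool = False) -> float:
        m = self.normalized if normalized else self.counts
        if m is None:
            raise ValueError("matrix not normalized yet")
        return m[self.index_of(i_label), self.index_of(j_label)]

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        m = self.normalized if normalized else self.counts
        return pd.DataFrame(m, index=list(self.labels), columns=list(self.labels))

    def to_long(self) -> pd.DataFrame:
        rows = []
        norm = self.normalized
        for i, li in enumerate(self.labels):
            for j, lj in enumerate(self.labels):
                rows.append(
                    {
                        "class_i": li,
                        "class_j": lj,
                        "count": int(self.counts[i, j]),
                        "normalized": float(norm[i, j]) if norm is not None else np.nan,
                    }
                )
        return pd.DataFrame(rows)


class UnclassifiableEventError(ValueError):
    pass


def mixing_matrix(
    events: Iterable[ContactEvent],
    class_of: ClassOf,
    labels: Sequence,
    axis: str = "custom",
    strict: bool = True,
    scope: Scope | None = None,
) -> MixingMatrix:
    """Tally contact events into a square ordered-pair count matrix.

    ``class_of(admission_id, date)`` returns a single class label, a set of
    labels (multi-class days, used for antibiotic ranks), or None/empty set
    for unclassifiable.  Under ``strict`` an unclassifiable participant
    raises; otherwise the event is excluded and counted in ``n_excluded``.
    """
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    n_excluded = 0
    for ev in events:
        ca = class_of(ev.admission_a, ev.date)
        cb = class_of(ev.admission_b, ev.date)
        set_a = ca if isinstance(ca, (set, frozenset)) else ({ca} if ca is not None else set())
        set_b = cb if isinstance(cb, (set, frozenset)) else ({cb} if cb is not None else set())
        if not set_a or not set_b:
            if strict:
                missing = ev.admission_a if not set_a else ev.admission_b
                raise UnclassifiableEventError(
                    f"admission {missing!r} unclassifiable on {ev.date} ({axis} axis)"
                )
            n_excluded += 1
            continue
        for ci in set_a:
            for cj in set_b:
                counts[idx[ci], idx[cj]] += 1
                counts[idx[cj], idx[ci]] += 1
    return MixingMatrix(
        axis=axis, labels=tuple(labels), counts=counts, scope=scope,
        n_excluded=n_excluded,
    )


def scope_events(
    bundle: EncounterBundle, scope: Scope, dedupe_same_day: bool = False
) -> list[ContactEvent]:
    """Contact events restricted to a scope's hospital, units and window."""
    stays = [
        s
        for s in bundle.stays_for_hospital(scope.hospital_id)
        if scope.admits_unit(s.unit_id, s.unit_type)
    ]
    rosters = daily_rosters(stays, scope.window)
    return enumerate_contacts(rosters, dedupe_same_day=dedupe_same_day)


def scope_admissions(bundle: EncounterBundle, scope: Scope) -> list[str]:
    """Admission ids with at least one in-scope roster day, sorted."""
    stays = [
        s
        for s in bundle.stays_for_hospital(scope.hospital_id)
        if scope.admits_unit(s.unit_id, s.unit_type)
    ]
    rosters = daily_rosters(stays, scope.window)
    active: set[str] = set()
    for members in rosters.values():
        active |= members
    return sorted(active)


def age_mixing(bundle: EncounterBundle, scope: Scope) -> MixingMatrix:
    """91x91 age mixing matrix (single-year classes 0..90)."""
    ages = {a.admission_id: a.age for a in bundle.admissions}
    events = scope_events(bundle, scope)
    return mixing_matrix(
        events, lambda aid, d: ages.get(aid), AGE_LABELS, axis="age", scope=scope
    )


def elixhauser_mixing(bundle: EncounterBundle, scope: Scope) -> MixingMatrix:
    """17x17 Elixhauser comorbidity-score mixing matrix (scores 0..16)."""
    scores = {a.admission_id: a.elixhauser for a in bundle.admissions}
    events = scope_events(bundle, scope)
    return mixing_matrix(
        events, lambda aid, d: scores.get(aid), ELIX_LABELS,
        axis="elixhauser", scope=scope,
    )


def _per_day_ranks(bundle: EncounterBundle) -> dict[tuple[str, date], set[str]]:
    m: dict[tuple[str, date], set[str]] = {}
    for e in bundle.exposures:
        m.setdefault((e.admission_id, e.date), set()).add(e.rank)
    return m


def _whole_stay_ranks(bundle: EncounterBundle) -> dict[str, set[str]]:
    m: dict[str, set[str]] = {}
    for e in bundle.exposures:
        m.setdefault(e.admission_id, set()).add(e.rank)
    return m


def abx_mixing(
    bundle: EncounterBundle,
    scope: Scope,
    timing_policy: str = "per_day",
    collapse_highest: bool = False,
) -> MixingMatrix:
    """4x4 antibiotic spectrum-rank mixing matrix plus excluded-event tally.

    ``per_day`` classifies each admission by the ranks recorded on the
    event's own date; ``whole_stay`` by all ranks recorded at any point in
    the admission.  Multi-rank days contribute the full cross-product of
    active ranks unless ``collapse_highest`` reduces each set to its single
    broadest rank.  Events where either participant has no active rank are
    excluded from the matrix and reported in ``n_excluded``.
    """
    if timing_policy not in ("per_day", "whole_stay"):
        raise ValueError(
            f"unknown timing_policy {timing_policy!r}; "
            "options: ('per_day', 'whole_stay')"
        )
    if timing_policy == "per_day":
        per_day = _per_day_ranks(bundle)

        def class_of(aid: str, d: date):
            ranks = per_day.get((aid, d), set())
            return _collapse(ranks) if collapse_highest else ranks
    else:
        whole = _whole_stay_ranks(bundle)

        def class_of(aid: str, d: date):
            ranks = whole.get(aid, set())
            return _collapse(ranks) if collapse_highest else ranks

    events = scope_events(bundle, scope)
    return mixing_matrix(
        events, class_of, ABX_RANKS, axis="abx", strict=False, scope=scope
    )


def _collapse(ranks: set[str]) -> set[str]:
    """Reduce a rank set to its single broadest (highest-priority) rank."""
    for r in reversed(ABX_RANKS):
        if r in ranks:
            return {r}
    return set()


def abx_none_ratio(bundle: EncounterBundle, scope: Scope) -> dict:
    """Ratio of contacts where neither participant is on any antibiotic.

    Classification is per day.  ``events_neither + events_any`` equals the
    total contact events in scope; the ratio is neither/any, reported as
    None (with ``ratio_missing=True``) when no contact involves an exposed
    patient.
    """
    per_day = _per_day_ranks(bundle)
    events = scope_events(bundle, scope)
    neither = 0
    for ev in events:
        if not per_day.get((ev.admission_a, ev.date)) and not per_day.get(
            (ev.admission_b, ev.date)
        ):
            neither += 1
    any_ = len(events) - neither
    return {
        "events_neither": neither,
        "events_any": any_,
        "ratio": (neither / any_) if any_ > 0 else None,
        "ratio_missing": any_ == 0,
    }


def normalize(matrix: MixingMatrix) -> MixingMatrix:
    """Min-max normalize: (x - min) / (max - min), cellwise over the matrix.

    The minimum cell maps to 0 and the maximum to 1.  A constant matrix
    (max == min) yields all zeros with ``degenerate_norm=True``.
    """
    counts = matrix.counts.astype(float)
    lo, hi = counts.min(), counts.max()
    if hi == lo:
        return _with_norm(matrix, np.zeros_like(counts), True)
    return _with_norm(matrix, (counts - lo) / (hi - lo), False)


def _with_norm(matrix: MixingMatrix, norm: np.ndarray, degenerate: bool) -> MixingMatrix:
    return MixingMatrix(
        axis=matrix.axis,
        labels=matrix.labels,
        counts=matrix.counts,
        scope=matrix.scope,
        normalized=norm,
        degenerate_norm=degenerate,
        n_excluded=matrix.n_excluded,
    )


def pattern_contingency(
    bundle: EncounterBundle, scope: Scope, grouping: str = "by_rank_combination"
) -> pd.DataFrame:
    """Admission-level tabulation of whole-stay antibiotic exposure.

    Each in-scope admission is counted once: under ``by_rank_combination``
    by the sorted set of ranks it was ever exposed to (e.g.
    ``narrow+extended``, or ``none``); under ``by_highest_rank`` by its
    single broadest rank.  Percentages sum to 100 over categories.
    """
    if grouping not in ("by_rank_combination", "by_highest_rank"):
        raise ValueError(
            f"unknown grouping {grouping!r}; "
            "options: ('by_rank_combination', 'by_highest_rank')"
        )
    whole = _whole_stay_ranks(bundle)
    admissions = scope_admissions(bundle, scope)
    cols = ["category", "n", "pct"]
    if not admissions:
        return pd.DataFrame(columns=cols)
    cats: dict[str, int] = {}
    for aid in admissions:
        ranks = whole.get(aid, set())
        if grouping == "by_highest_rank":
            ranks = _collapse(ranks)
        if not ranks:
            label = "none"
        else:
            label = "+".join(r for r in ABX_RANKS if r in ranks)
        cats[label] = cats.get(label, 0) + 1
    total = len(admissions)
    rows = [
        {"category": c, "n": n, "pct": 100.0 * n / total}
        for c, n in sorted(cats.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=cols)


def plot_matrix(matrix: MixingMatrix, path, normalized: bool = True) -> None:
    """Save a heatmap PNG of the (normalized) matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = matrix.normalized if (normalized and matrix.normalized is not None) else matrix.counts
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(m, origin="lower", cmap="viridis")
    ax.set_xlabel(matrix.axis)
    ax.set_ylabel(matrix.axis)
    if len(matrix.labels) <= 8:
        ax.set_xticks(range(len(matrix.labels)), matrix.labels)
        ax.set_yticks(range(len(matrix.labels)), matrix.labels)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
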