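"""Core data types and delimited-text I/O.

Drugs are addressed by 0-based integer index everywhere inside the
package; identifier strings appear only at file boundaries.  Event
classes are coded 0..R-1 in descending order of sample count (ties
broken lexicographically by their (mechanism, action) label), matching
the convention of plotting event 1 as the most frequent.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

SOURCE_TAGS = ("structure", "target", "enzyme", "pathway")


class ValidationError(ValueError):
    """Raised when an input file or in-memory structure violates a contract."""


@dataclass(frozen=True)
class DrugIndex:
    """Stable bijection between drug identifier strings and 0..n-1."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = [d for d, c in Counter(self.ids).items() if c > 1]
            raise ValidationError(f"duplicate drug identifiers: {dupes[:5]}")
        object.__setattr__(self, "_pos", {d: i for i, d in enumerate(self.ids)})

    def __len__(self) -> int:
        return len(self.ids)

    def position(self, drug_id: str) -> int:
        try:
            return self._pos[drug_id]
        except KeyError:
            raise ValidationError(f"unknown drug identifier: {drug_id!r}") from None

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._pos


@dataclass(frozen=True)
class BinaryFeatureMatrix:
    """Presence/absence bits of feature items (drugs x items) for one source."""

    source: str
    drugs: DrugIndex
    items: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if v.shape[0] != len(self.drugs):
            raise ValidationError(
                f"row count {v.shape[0]} != number of drugs {len(self.drugs)}"
            )
        if v.shape[1] != len(self.items):
            raise ValidationError(
                f"column count {v.shape[1]} != number of items {len(self.items)}"
            )
        bad = np.argwhere((v != 0) & (v != 1))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"non-binary entry {v[i, j]!r} at drug {self.drugs.ids[i]!r}, "
                f"item {self.items[j]!r}"
            )
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class EventCatalog:
    """The R interaction-event classes, id-ordered by descending frequency."""

    labels: tuple[tuple[str, str], ...]  # (mechanism, action) per event id
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValidationError("labels and counts length mismatch")
        order = sorted(
            range(len(self.counts)), key=lambda k: (-self.counts[k], self.labels[k])
        )
        if order != list(range(len(self.counts))):
            raise ValidationError("event ids must be ordered by descending count")
        object.__setattr__(
            self, "_id_of", {lab: i for i, lab in enumerate(self.labels)}
        )

    @property
    def n_events(self) -> int:
        return len(self.labels)

    def id_of(self, mechanism: str, action: str) -> int:
        try:
            return self._id_of[(mechanism, action)]
        except KeyError:
            raise ValidationError(
                f"unknown event label: ({mechanism!r}, {action!r})"
            ) from None


@dataclass(frozen=True)
class EventEdgeList:
    """Undirected, event-typed drug pairs stored canonically with i < j."""

    edges: tuple[tuple[int, int, int], ...]
    n_events: int

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for i, j, r in self.edges:
            if i == j:
                raise ValidationError(f"self-interaction on drug index {i}")
            if i > j:
                raise ValidationError(f"edge ({i},{j}) not in canonical i<j order")
            if not 0 <= r < self.n_events:
                raise ValidationError(f"event id {r} outside 0..{self.n_events - 1}")
            if (i, j) in seen:
                raise ValidationError(f"duplicate drug pair ({i},{j})")
            seen.add((i, j))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def labels(self) -> np.ndarray:
        return np.array([r for _, _, r in self.edges], dtype=np.int64)

    def pairs(self) -> np.ndarray:
        return np.array([(i, j) for i, j, _ in self.edges], dtype=np.int64).reshape(-1, 2)

    def subset(self, indices: Sequence[int]) -> "EventEdgeList":
        return EventEdgeList(tuple(self.edges[k] for k in indices), self.n_events)


def _sniff_delimiter(sample: str) -> str:
    # restrict to the two supported delimiters; csv.Sniffer is too permissive
    header = sample.splitlines()[0] if sample else ""
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_feature_matrix(path: str | Path, source: str) -> BinaryFeatureMatrix:
    """Read a drugs x items binary matrix from CSV/TSV.

    Expects a header row of item labels and a first column of drug ids.
    Delimiter (comma or tab) is auto-detected.  Rejects duplicate drug
    ids and any cell that is not exactly 0 or 1, naming the offender.
    """
    text = Path(path).read_text(encoding="utf-8")
    delim = _sniff_delimiter(text)
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    rows = [row for row in rows if row and any(c.strip() for c in row)]
    if len(rows) < 1 or len(rows[0]) < 2:
        raise ValidationError(f"{path}: expected header of item labels and >=1 item column")
    items = tuple(c.strip() for c in rows[0][1:])
    drug_ids = []
    data = np.empty((len(rows) - 1, len(items)), dtype=np.uint8)
    for ri, row in enumerate(rows[1:]):
        if len(row) != len(items) + 1:
            raise ValidationError(f"{path}: row {ri + 2} has {len(row)} fields, expected {len(items) + 1}")
        drug_ids.append(row[0].strip())
        for ci, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell not in ("0", "1"):
                raise ValidationError(
                    f"{path}: non-binary value {cell!r} at drug {row[0].strip()!r}, "
                    f"item {items[ci]!r}"
                )
            data[ri, ci] = cell == "1"
    return BinaryFeatureMatrix(source, DrugIndex(tuple(drug_ids)), items, data)


def write_feature_matrix(matrix: BinaryFeatureMatrix, path: str | Path, delimiter: str = ",") -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["drug_id", *matrix.items])
        for i, drug in enumerate(matrix.drugs.ids):
            w.writerow([drug, *matrix.values[i].tolist()])


def parse_event_quadruples(
    rows: Iterable[tuple[str, str, str, str]], drugs: DrugIndex
) -> tuple[EventCatalog, EventEdgeList]:
    """Turn (drug A, drug B, mechanism, action) records into catalog + edge list.

    Event ids are assigned by descending sample count (lexicographic label
    tie-break); edges are canonicalized to i < j.  Unknown drugs,
    self-pairs and duplicate unordered pairs are rejected.
    """
    rows = list(rows)
    label_counts: Counter[tuple[str, str]] = Counter((m, a) for _, _, m, a in rows)
    ordered = sorted(label_counts, key=lambda lab: (-label_counts[lab], lab))
    catalog = EventCatalog(tuple(ordered), tuple(label_counts[lab] for lab in ordered))

    edges: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for a, b, mech, act in rows:
        i, j = drugs.position(a), drugs.position(b)
        if i == j:
            raise ValidationError(f"self-interaction for drug {a!r}")
        if i > j:
            i, j = j, i
        if (i, j) in seen:
            raise ValidationError(
                f"duplicate unordered pair ({drugs.ids[i]!r}, {drugs.ids[j]!r})"
            )
        seen.add((i, j))
        edges.append((i, j, catalog.id_of(mech, act)))
    return catalog, EventEdgeList(tuple(edges), catalog.n_events)


def read_edge_list(path: str | Path, drugs: DrugIndex) -> tuple[EventCatalog, EventEdgeList]:
    """Read DDI records from CSV/TSV.

    Two layouts are accepted, detected from the header: quadruples with
    columns (drug_a, drug_b, mechanism, action), or pre-coded triples
    (drug_a, drug_b, event_id) whose ids are re-used verbatim.
    """
    text = Path(path).read_text(encoding="utf-8")
    delim = _sniff_delimiter(text)
    rows = [r for r in csv.reader(io.StringIO(text), delimiter=delim) if r and any(c.strip() for c in r)]
    if not rows:
        raise ValidationError(f"{path}: empty edge file")
    header = [c.strip().lower() for c in rows[0]]
    body = rows[1:]
    if len(header) >= 4:
        quads = [(r[0].strip(), r[1].strip(), r[2].strip(), r[3].strip()) for r in body]
        return parse_event_quadruples(quads, drugs)
    if len(header) == 3:
        trips: list[tuple[int, int, int]] = []
        seen: set[tuple[int, int]] = set()
        counts: Counter[int] = Counter()
        for r in body:
            i, j = drugs.position(r[0].strip()), drugs.position(r[1].strip())
            rid = int(r[2])
            if i == j:
                raise ValidationError(f"self-interaction for drug {r[0]!r}")
            if i > j:
                i, j = j, i
            if (i, j) in seen:
                raise ValidationError(f"duplicate unordered pair in {path}: {r[0]},{r[1]}")
            seen.add((i, j))
            counts[rid] += 1
            trips.append((i, j, rid))
        n_events = max(counts) + 1 if counts else 0
        labels = tuple((f"event_{r}", "coded") for r in range(n_events))
        cat_counts = tuple(counts.get(r, 0) for r in range(n_events))
        # pre-coded ids are trusted as-is; the descending-count invariant is
        # only enforced for catalogs built from quadruples
        catalog = object.__new__(EventCatalog)
        object.__setattr__(catalog, "labels", labels)
        object.__setattr__(catalog, "counts", cat_counts)
        object.__setattr__(catalog, "_id_of", {lab: k for k, lab in enumerate(labels)})
        return catalog, EventEdgeList(tuple(trips), n_events)
    raise ValidationError(f"{path}: expected 3 (triples) or >=4 (quadruples) columns")


def write_edge_list(edges: EventEdgeList, drugs: DrugIndex, path: str | Path, delimiter: str = ",") -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["drug_a", "drug_b", "event_id"])
        for i, j, r in edges.edges:
            w.writerow([drugs.ids[i], drugs.ids[j], r])


def save_tensor_npz(path: str | Path, values: np.ndarray, drugs: DrugIndex, source: str) -> None:
    """Persist an embedding tensor or pair-feature matrix with metadata."""
    np.savez(
        path,
        values=values,
        drug_ids=np.array(drugs.ids, dtype=object),
        source=np.array(source),
    )


def load_tensor_npz(path: str | Path) -> tuple[np.ndarray, DrugIndex, str]:
    with np.load(path, allow_pickle=True) as z:
        return (
            z["values"],
            DrugIndex(tuple(str(d) for d in z["drug_ids"])),
            str(z["source"]),
        )
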