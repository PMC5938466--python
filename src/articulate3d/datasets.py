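"""Multi-specimen landmark arrays, TPS I/O, specimen matching and joining.

The in-memory container mirrors the ``p x 3 x n`` convention of
geometric-morphometrics software: a coordinate block indexed by
(landmark, axis, specimen) plus an ordered list of unique specimen
identifiers.  TPS reading and writing is native (plain-text ``LM3=`` /
``ID=`` / ``SCALE=`` records), and round-trips coordinates at full
float precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .errors import SpecimenMatchError, TPSFormatError

__all__ = [
    "LandmarkArray",
    "JoinedDataset",
    "StructurePair",
    "read_tps",
    "write_tps",
    "match_datasets",
    "join_arrays",
    "translate",
]


@dataclass
class LandmarkArray:
    """All landmarks of one structure across specimens.

    Parameters
    ----------
    coords : ndarray, shape (landmark_count, 3, specimen_count)
        Cartesian coordinates in any consistent length unit.
    specimen_ids : list of str
        Unique identifiers, one per specimen, in storage order.
    """

    coords: np.ndarray
    specimen_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != 3:
            raise ValueError(
                f"coords must have shape (landmarks, 3, specimens), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        self.specimen_ids = [str(s) for s in self.specimen_ids]
        if len(self.specimen_ids) != self.coords.shape[2]:
            raise ValueError(
                f"{len(self.specimen_ids)} specimen ids for {self.coords.shape[2]} specimens"
            )
        if len(set(self.specimen_ids)) != len(self.specimen_ids):
            dupes = sorted(
                {s for s in self.specimen_ids if self.specimen_ids.count(s) > 1}
            )
            raise ValueError(f"duplicate specimen ids: {dupes}")

    @property
    def landmark_count(self) -> int:
        return self.coords.shape[0]

    @property
    def specimen_count(self) -> int:
        return self.coords.shape[2]

    def specimen_index(self, key: int | str) -> int:
        if isinstance(key, str):
            try:
                return self.specimen_ids.index(key)
            except ValueError:
                raise KeyError(f"no specimen named {key!r}") from None
        n = self.specimen_count
        if not -n <= key < n:
            raise IndexError(f"specimen index {key} out of range for {n} specimens")
        return key % n

    def specimen(self, key: int | str) -> np.ndarray:
        """Coordinates of one specimen as a copy of shape (landmarks, 3)."""
        return self.coords[:, :, self.specimen_index(key)].copy()

    def subset(self, ids: list[str]) -> "LandmarkArray":
        """Restrict/reorder to the given specimen ids (all must exist)."""
        idx = [self.specimen_index(s) for s in ids]
        return replace(self, coords=self.coords[:, :, idx].copy(),
                       specimen_ids=list(ids))

    def copy(self) -> "LandmarkArray":
        return replace(self, coords=self.coords.copy(),
                       specimen_ids=list(self.specimen_ids))


@dataclass
class JoinedDataset(LandmarkArray):
    """Per-specimen concatenation of two rotated structures.

    ``provenance`` tags each landmark row with its source structure
    (1 or 2); :meth:`split` inverts the join exactly.
    """

    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        self.provenance = np.asarray(self.provenance, dtype=int)
        if self.provenance.shape != (self.landmark_count,):
            raise ValueError("provenance must tag every landmark")
        if not set(np.unique(self.provenance)) <= {1, 2}:
            raise ValueError("provenance tags must be 1 or 2")

    def split(self) -> tuple[LandmarkArray, LandmarkArray]:
        """Recover the two source structures by provenance tag."""
        m1 = self.provenance == 1
        m2 = self.provenance == 2
        return (
            LandmarkArray(self.coords[m1].copy(), list(self.specimen_ids)),
            LandmarkArray(self.coords[m2].copy(), list(self.specimen_ids)),
        )


@dataclass
class StructurePair:
    """Two landmark arrays with identical, identically-ordered specimen ids
    (the product of :func:`match_datasets`)."""

    data_1: LandmarkArray
    data_2: LandmarkArray

    def __post_init__(self) -> None:
        if self.data_1.specimen_ids != self.data_2.specimen_ids:
            raise ValueError(
                "StructurePair requires identical specimen ids in identical "
                "order; run match_datasets first"
            )

    @property
    def specimen_ids(self) -> list[str]:
        return self.data_1.specimen_ids

    @property
    def specimen_count(self) -> int:
        return self.data_1.specimen_count


# ---------------------------------------------------------------------------
# TPS I/O


def read_tps(path) -> LandmarkArray:
    """Read a 3D TPS landmark file.

    Accepts the common dialect: per specimen an ``LM3=n`` line, ``n``
    whitespace-separated coordinate triples, an optional ``SCALE=s`` line
    (applied multiplicatively) and an ``ID=label`` line.  Keywords are
    case-insensitive; blank lines, ``IMAGE=`` lines and CRLF endings are
    tolerated.  2D ``LM=`` records are rejected explicitly; a missing ID
    is auto-labelled with a warning.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()

    records: list[dict] = []
    cur: dict | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        keyword = key.strip().upper() if _ else None
        if keyword == "LM3":
            try:
                count = int(value.strip())
            except ValueError:
                raise TPSFormatError(f"line {lineno}: bad LM3 count {value!r}")
            cur = {"count": count, "coords": [], "id": None, "scale": None,
                   "line": lineno}
            records.append(cur)
        elif keyword == "LM":
            raise TPSFormatError(
                f"line {lineno}: 2D 'LM=' record found; only 3D 'LM3=' files "
                "are supported"
            )
        elif keyword == "ID":
            if cur is None:
                raise TPSFormatError(f"line {lineno}: ID= before any LM3= record")
            cur["id"] = value.strip()
        elif keyword == "SCALE":
            if cur is None:
                raise TPSFormatError(f"line {lineno}: SCALE= before any LM3= record")
            try:
                cur["scale"] = float(value.strip())
            except ValueError:
                raise TPSFormatError(f"line {lineno}: bad SCALE value {value!r}")
        elif keyword == "IMAGE":
            continue
        elif keyword is not None and keyword.replace("_", "").isalpha():
            # unknown keyword record (e.g. CURVES=) — out of scope, skip
            continue
        else:
            if cur is None:
                raise TPSFormatError(
                    f"line {lineno}: coordinate data before any LM3= record"
                )
            parts = line.split()
            if len(parts) != 3:
                raise TPSFormatError(
                    f"line {lineno}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                cur["coords"].append([float(p) for p in parts])
            except ValueError:
                raise TPSFormatError(f"line {lineno}: unparseable coordinates {line!r}")

    if not records:
        raise TPSFormatError(f"{path}: no LM3= records found")

    ids: list[str] = []
    blocks: list[np.ndarray] = []
    expected = records[0]["count"]
    for i, rec in enumerate(records, start=1):
        label = rec["id"]
        if label is None or label == "":
            label = f"specimen_{i}"
            warnings.warn(
                f"{path}: record {i} (line {rec['line']}) has no ID=; "
                f"auto-labelled {label!r}",
                stacklevel=2,
            )
        if len(rec["coords"]) != rec["count"]:
            raise TPSFormatError(
                f"specimen {label!r}: LM3={rec['count']} but "
                f"{len(rec['coords'])} coordinate lines"
            )
        if rec["count"] != expected:
            raise TPSFormatError(
                f"specimen {label!r}: landmark count {rec['count']} differs "
                f"from first specimen's {expected}"
            )
        block = np.asarray(rec["coords"], dtype=float)
        if rec["scale"] is not None:
            block = block * rec["scale"]
        ids.append(label)
        blocks.append(block)

    coords = np.stack(blocks, axis=2)
    return LandmarkArray(coords, ids)


def write_tps(data: LandmarkArray, path) -> None:
    """Write a landmark array as a 3D TPS file.

    One ``LM3=`` block per specimen, coordinates at full float
    precision (shortest round-trip repr), then ``ID=``.  No SCALE line
    is written: rotated coordinates are already in final units.  Output
    is byte-stable for identical input.
    """
    if data.landmark_count == 0:
        raise ValueError("cannot write an array with zero landmarks")
    lines: list[str] = []
    for i, sid in enumerate(data.specimen_ids):
        lines.append(f"LM3={data.landmark_count}")
        for row in data.coords[:, :, i]:
            lines.append(" ".join(repr(float(x)) for x in row))
        lines.append(f"ID={sid}")
        lines.append("")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------------------
# matching / joining / translating


def match_datasets(d1: LandmarkArray, d2: LandmarkArray) -> StructurePair:
    """Restrict two arrays to their common specimens, in ``d1``'s order.

    Specimens present in only one input are dropped with a warning that
    names them; an empty intersection raises :class:`SpecimenMatchError`.
    Idempotent: matching an already-matched pair changes nothing.
    """
    set1 = set(d1.specimen_ids)
    set2 = set(d2.specimen_ids)
    common = [s for s in d1.specimen_ids if s in set2]
    if not common:
        raise SpecimenMatchError(
            "datasets share no specimen identifiers; nothing to match"
        )
    dropped = sorted((set1 | set2) - (set1 & set2))
    if dropped:
        warnings.warn(
            "specimens present in only one dataset were dropped: "
            + ", ".join(dropped),
            stacklevel=2,
        )
    return StructurePair(d1.subset(common), d2.subset(common))


def join_arrays(d1: LandmarkArray, d2: LandmarkArray) -> JoinedDataset:
    """Concatenate two specimen-matched arrays along the landmark axis.

    Structure 1's landmarks come first; provenance tags record the
    source structure so the join is exactly invertible via
    :meth:`JoinedDataset.split`.
    """
    if d1.landmark_count == 0 or d2.landmark_count == 0:
        raise ValueError("cannot join an array with zero landmarks")
    if d1.specimen_ids != d2.specimen_ids:
        raise ValueError(
            "specimen ids differ or are ordered differently; "
            "run match_datasets first"
        )
    coords = np.concatenate([d1.coords, d2.coords], axis=0)
    provenance = np.concatenate(
        [np.ones(d1.landmark_count, dtype=int),
         np.full(d2.landmark_count, 2, dtype=int)]
    )
    return JoinedDataset(coords, list(d1.specimen_ids), provenance)


def translate(data: LandmarkArray, landmark: int,
              origin=(0.0, 0.0, 0.0)) -> LandmarkArray:
    """Translate every specimen so the chosen landmark sits on ``origin``.

    ``landmark`` is **1-based**, matching the user-facing convention of
    the articulation API and the CLI.  Each specimen is translated by
    its own displacement, so after this step the chosen landmark is at
    ``origin`` in every specimen while all within-specimen geometry is
    unchanged.
    """
    if not 1 <= landmark <= data.landmark_count:
        raise IndexError(
            f"landmark {landmark} out of range 1..{data.landmark_count}"
        )
    out = np.empty_like(data.coords)
    for i in range(data.specimen_count):
        out[:, :, i] = geometry.translate_points(
            data.coords[:, :, i], landmark - 1, origin
        )
    return replace(data, coords=out, specimen_ids=list(data.specimen_ids))
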