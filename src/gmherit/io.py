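"""Readers and writers for landmark (TPS, wide CSV) and pedigree files.

TPS dialect: each record starts with an ``LM=<k>`` line, followed by k
whitespace-separated ``x y`` lines, then optional ``ID=``, ``SCALE=`` and
``IMAGE=`` key lines. Keys are matched case-insensitively; unknown keys are
ignored with a warning. Coordinates are kept as digitized unless scaling is
requested explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "Pedigree",
    "read_landmarks",
    "write_landmarks",
    "read_pedigree",
    "write_pedigree",
]

logger = logging.getLogger("gmherit")

_KNOWN_TPS_KEYS = {"LM", "ID", "SCALE", "IMAGE"}


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmarks in digitizing units.

    Landmark order is the homology order: index i is the same anatomical
    point on every specimen in a dataset.
    """

    specimen_id: str
    landmarks: np.ndarray  # (k, 2)
    scale: Optional[float] = None

    def __post_init__(self):
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.ndim != 2 or self.landmarks.shape[1] != 2:
            raise ValueError("landmarks must be a (k, 2) array")
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError(f"non-finite coordinate in specimen {self.specimen_id!r}")

    @property
    def k(self) -> int:
        return self.landmarks.shape[0]


class TPSParseError(ValueError):
    pass


def _check_common_k(configs: Sequence[LandmarkConfiguration]) -> None:
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValueError(
            f"inconsistent landmark counts across records: {sorted(ks)}"
        )


def _read_tps(path: Path, apply_scale: bool, flip_y: bool) -> List[LandmarkConfiguration]:
    configs: List[LandmarkConfiguration] = []
    lm_expected: Optional[int] = None
    coords: List[List[float]] = []
    meta: dict = {}
    record_start = 0

    def finish(lineno: int) -> None:
        nonlocal lm_expected, coords, meta
        if lm_expected is None:
            return
        if len(coords) != lm_expected:
            raise TPSParseError(
                f"record starting at line {record_start} "
                f"(ID={meta.get('ID', '?')}): LM={lm_expected} but "
                f"{len(coords)} coordinate lines found"
            )
        xy = np.array(coords, dtype=float)
        scale = float(meta["SCALE"]) if "SCALE" in meta else None
        if apply_scale and scale is not None:
            xy = xy * scale
        if flip_y:
            xy = xy * np.array([1.0, -1.0])
        sid = meta.get("ID", f"record_{len(configs) + 1}")
        configs.append(LandmarkConfiguration(sid, xy, scale=scale))
        lm_expected, coords, meta = None, [], {}

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if "=" in line and not _looks_numeric(line):
                key, _, value = line.partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "LM":
                    finish(lineno)
                    record_start = lineno
                    try:
                        lm_expected = int(value)
                    except ValueError:
                        raise TPSParseError(f"line {lineno}: bad LM count {value!r}")
                elif key in _KNOWN_TPS_KEYS:
                    if lm_expected is None:
                        raise TPSParseError(
                            f"line {lineno}: {key}= before any LM= record"
                        )
                    meta[key] = value
                else:
                    logger.warning("ignoring unknown TPS key %r at line %d", key, lineno)
            else:
                if lm_expected is None:
                    raise TPSParseError(
                        f"line {lineno}: coordinates before any LM= record"
                    )
                parts = line.split()
                if len(parts) != 2:
                    raise TPSParseError(
                        f"line {lineno}: expected 'x y', got {line!r}"
                    )
                try:
                    coords.append([float(parts[0]), float(parts[1])])
                except ValueError:
                    raise TPSParseError(
                        f"line {lineno}: non-numeric coordinate in {line!r}"
                    )
                if len(coords) > lm_expected:
                    raise TPSParseError(
                        f"record starting at line {record_start}: more than "
                        f"LM={lm_expected} coordinate lines"
                    )
    finish(-1)
    return configs


def _looks_numeric(line: str) -> bool:
    head = line.split()[0]
    try:
        float(head)
        return True
    except ValueError:
        return False


def _read_landmark_csv(path: Path, flip_y: bool) -> List[LandmarkConfiguration]:
    df = pd.read_csv(path, comment="#")
    if "specimen_id" not in df.columns:
        raise ValueError("landmark CSV must have a 'specimen_id' column")
    coord_cols = [c for c in df.columns if c != "specimen_id"]
    if len(coord_cols) % 2 != 0 or not coord_cols:
        raise ValueError("landmark CSV needs paired x1,y1,...,xk,yk columns")
    k = len(coord_cols) // 2
    expected = [f"{ax}{i}" for i in range(1, k + 1) for ax in ("x", "y")]
    if sorted(coord_cols) != sorted(expected):
        raise ValueError(f"landmark CSV columns must be {expected}")
    configs = []
    for _, row in df.iterrows():
        xy = np.column_stack(
            [row[[f"x{i}" for i in range(1, k + 1)]].to_numpy(float),
             row[[f"y{i}" for i in range(1, k + 1)]].to_numpy(float)]
        )
        if flip_y:
            xy = xy * np.array([1.0, -1.0])
        configs.append(LandmarkConfiguration(str(row["specimen_id"]), xy))
    return configs


def read_landmarks(
    path,
    format: Optional[str] = None,
    apply_scale: bool = False,
    flip_y: bool = False,
) -> List[LandmarkConfiguration]:
    """Read landmark configurations from a TPS or wide-CSV file.

    ``format`` is 'tps' or 'csv'; inferred from the suffix when omitted.
    ``apply_scale`` multiplies coordinates by each record's SCALE (TPS only);
    raw digitized coordinates are kept by default. ``flip_y`` negates y for
    image-derived files with a top-left origin.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "tps":
        configs = _read_tps(path, apply_scale, flip_y)
    elif fmt == "csv":
        configs = _read_landmark_csv(path, flip_y)
    else:
        raise ValueError(f"unknown landmark format {fmt!r} (use 'tps' or 'csv')")
    _check_common_k(configs)
    logger.info("read %d configurations (%d landmarks) from %s",
                len(configs), configs[0].k if configs else 0, path)
    return configs


def write_landmarks(path, configs: Sequence[LandmarkConfiguration],
                    format: Optional[str] = None) -> None:
    """Write configurations as TPS or wide CSV (format inferred from suffix)."""
    path = Path(path)
    _check_common_k(configs)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "tps":
        with open(path, "w", encoding="utf-8") as fh:
            for c in configs:
                fh.write(f"LM={c.k}\n")
                for x, y in c.landmarks:
                    fh.write(f"{x:.12g} {y:.12g}\n")
                fh.write(f"ID={c.specimen_id}\n")
                if c.scale is not None:
                    fh.write(f"SCALE={c.scale:.12g}\n")
    elif fmt == "csv":
        k = configs[0].k if configs else 0
        cols = {"specimen_id": [c.specimen_id for c in configs]}
        for i in range(k):
            cols[f"x{i + 1}"] = [c.landmarks[i, 0] for c in configs]
            cols[f"y{i + 1}"] = [c.landmarks[i, 1] for c in configs]
        pd.DataFrame(cols).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown landmark format {fmt!r}")


@dataclass
class Pedigree:
    """Colony and patriline assignment of every specimen.

    One row per specimen; each specimen belongs to exactly one colony and one
    patriline (its paternal half-sib family). ``queen_id`` is optional.
    """

    table: pd.DataFrame  # columns: specimen_id, colony_id, patriline_id[, queen_id]

    def __post_init__(self):
        required = ["specimen_id", "colony_id", "patriline_id"]
        for col in required:
            if col not in self.table.columns:
                raise ValueError(f"pedigree is missing required column {col!r}")
        dup = self.table["specimen_id"][self.table["specimen_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate specimen_id in pedigree: {dup.iloc[0]!r}")
        self.table = self.table.reset_index(drop=True)
        for col in required:
            self.table[col] = self.table[col].astype(str)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> List[str]:
        return list(self.table["specimen_id"])

    @property
    def colonies(self) -> List[str]:
        return sorted(self.table["colony_id"].unique())

    @property
    def patrilines(self) -> List[str]:
        return sorted(self.table["patriline_id"].unique())

    def lookup(self, specimen_id: str) -> tuple:
        row = self.table[self.table["specimen_id"] == str(specimen_id)]
        if row.empty:
            raise KeyError(f"specimen {specimen_id!r} not in pedigree")
        r = row.iloc[0]
        return (r["colony_id"], r["patriline_id"])

    def patriline_labels(self, id_order: Optional[Sequence[str]] = None) -> List[str]:
        """Patriline label per specimen, in ``id_order`` (or table order)."""
        if id_order is None:
            return list(self.table["patriline_id"])
        return [self.lookup(i)[1] for i in id_order]


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV (header: specimen_id, colony_id, patriline_id
    [, queen_id]).  Columns are matched by name, not position."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    ped = Pedigree(df)
    if len(ped) == 0:
        logger.warning("pedigree %s contains a header but no records", path)
    else:
        logger.info("pedigree %s: %d specimens, colonies=%s, patrilines=%s",
                    path, len(ped), ped.colonies, ped.patrilines)
    return ped


def write_pedigree(path, pedigree: Pedigree) -> None:
    pedigree.table.to_csv(path, index=False)
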