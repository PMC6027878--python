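"""Landmark configuration I/O: TPS files (tpsDig dialect), CSV tables and metadata.

Coordinates are stored in millimetres.  TPS blocks carry pixel coordinates
plus an optional ``SCALE=`` factor (mm per pixel, default 1.0) which is
applied at read time, so every :class:`Specimen` in memory is in mm.

Specimen metadata (stage / genotype / sex) lives in a sidecar CSV keyed by
specimen id, because the TPS format has no metadata fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("larva", "pupa", "adult")
SEXES = ("F", "M", "unknown")

N_LANDMARKS = 17
N_FIXED = 8


class TPSFormatError(ValueError):
    """Raised when a TPS file violates the expected schema."""


class MetadataError(KeyError):
    """Raised when specimen ids cannot be matched to metadata records."""


@dataclass(frozen=True)
class LandmarkScheme:
    """Fixed-landmark / semilandmark layout of a configuration.

    Landmark indices are 0-based internally.  Rows 0-7 are fixed landmarks,
    rows 8-16 are semilandmarks.  Each semilandmark group is an ordered run
    of semilandmarks between two fixed anchor landmarks along a margin
    curve: the anterior margin carries semilandmarks 8..13 between anchors
    0 and 2, the posterior margin carries 14..16 between anchors 4 and 6
    (i.e. 9-14 between landmarks 1 and 3, and 15-17 between 5 and 7 in
    1-based labelling).
    """

    n_landmarks: int = N_LANDMARKS
    n_fixed: int = N_FIXED
    semilandmark_groups: tuple[tuple[int, tuple[int, ...], int], ...] = (
        (0, (8, 9, 10, 11, 12, 13), 2),
        (4, (14, 15, 16), 6),
    )

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for start, semis, end in self.semilandmark_groups:
            if start >= self.n_fixed or end >= self.n_fixed:
                raise ValueError("group anchors must be fixed landmarks")
            for s in semis:
                if s < self.n_fixed or s >= self.n_landmarks:
                    raise ValueError(f"semilandmark index {s} out of range")
                if s in seen:
                    raise ValueError(f"semilandmark {s} in more than one group")
                seen.add(s)
        expected = set(range(self.n_fixed, self.n_landmarks))
        if seen != expected:
            raise ValueError("every semilandmark must belong to exactly one group")

    @property
    def semilandmarks(self) -> tuple[int, ...]:
        return tuple(s for _, semis, _ in self.semilandmark_groups for s in semis)

    def group_sequence(self, group: int) -> tuple[int, ...]:
        """Ordered vertex run anchor..semis..anchor for one margin group."""
        start, semis, end = self.semilandmark_groups[group]
        return (start, *semis, end)


DEFAULT_SCHEME = LandmarkScheme()


@dataclass
class Specimen:
    """A single wing: one 17x2 landmark configuration plus labels.

    ``landmarks`` rows follow the scheme ordering (fixed landmarks first,
    then the semilandmark runs); units are mm after reading.
    """

    id: str
    stage: str
    genotype: str
    landmarks: np.ndarray
    sex: str = "unknown"
    scale: float = 1.0
    scheme: LandmarkScheme = field(default=DEFAULT_SCHEME, repr=False)

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (self.scheme.n_landmarks, 2):
            raise ValueError(
                f"specimen {self.id!r}: landmarks must be "
                f"{self.scheme.n_landmarks}x2, got {self.landmarks.shape}"
            )
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError(f"specimen {self.id!r}: non-finite coordinates")
        if not self.scale > 0:
            raise ValueError(f"specimen {self.id!r}: scale must be > 0")
        if self.stage not in STAGES:
            raise ValueError(f"specimen {self.id!r}: unknown stage {self.stage!r}")
        if self.sex not in SEXES:
            raise ValueError(f"specimen {self.id!r}: unknown sex {self.sex!r}")

    def copy(self) -> "Specimen":
        return replace(self, landmarks=self.landmarks.copy())


_KNOWN_TPS_KEYS = {"LM", "IMAGE", "ID", "SCALE"}


def _parse_tps_blocks(path: Path) -> list[dict]:
    """Split a TPS file into raw blocks (one per LM= key)."""
    blocks: list[dict] = []
    current: dict | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            key, eq, value = line.partition("=")
            if eq and key.strip().upper() in _KNOWN_TPS_KEYS:
                key = key.strip().upper()
                if key == "LM":
                    current = {"lm": int(value), "coords": [], "lineno": lineno}
                    blocks.append(current)
                    continue
                if current is None:
                    raise TPSFormatError(f"{path}:{lineno}: {key}= before any LM= block")
                current[key.lower()] = value.strip()
                continue
            if eq and not _is_coordinate_line(line):
                # unknown KEY=value line: tpsDig variants differ, keep going
                logger.warning("%s:%d: ignoring unknown TPS key %r", path, lineno, key.strip())
                continue
            if current is None:
                raise TPSFormatError(f"{path}:{lineno}: coordinates before any LM= block")
            parts = line.split()
            if len(parts) != 2:
                raise TPSFormatError(f"{path}:{lineno}: expected 'x y', got {line!r}")
            try:
                xy = (float(parts[0]), float(parts[1]))
            except ValueError as exc:
                raise TPSFormatError(f"{path}:{lineno}: non-numeric coordinate {line!r}") from exc
            current["coords"].append(xy)
    return blocks


def _is_coordinate_line(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def read_tps(
    path: str | Path,
    metadata: str | Path | pd.DataFrame | Mapping[str, Mapping[str, str]] | None = None,
    scheme: LandmarkScheme = DEFAULT_SCHEME,
    flip_y: bool = False,
) -> list[Specimen]:
    """Read specimens from a TPS file.

    Parameters
    ----------
    path
        TPS file with ``LM=17`` blocks.  ``SCALE=`` (mm/pixel) defaults to
        1.0; coordinates are multiplied by it.  ``ID=`` or, failing that,
        ``IMAGE=`` names the specimen.
    metadata
        Sidecar mapping id -> stage/genotype/sex.  May be a CSV path or
        DataFrame with columns ``id, stage, genotype, sex``, or a mapping.
        If None, all specimens get stage/genotype placeholders and an
        error is raised (metadata is required to build Specimens).
    flip_y
        Negate y coordinates at read time, for sources digitized with an
        image-origin (top-left) convention mixed with others.
    """
    path = Path(path)
    meta = _coerce_metadata(metadata)
    blocks = _parse_tps_blocks(path)
    specimens: list[Specimen] = []
    seen_ids: set[str] = set()
    unmatched: list[str] = []
    for i, block in enumerate(blocks):
        n = block["lm"]
        if n != scheme.n_landmarks:
            raise TPSFormatError(
                f"{path}: block {i + 1} (line {block['lineno']}) declares LM={n}, "
                f"expected {scheme.n_landmarks}"
            )
        if len(block["coords"]) != n:
            raise TPSFormatError(
                f"{path}: block {i + 1} has {len(block['coords'])} coordinate "
                f"lines, expected {n}"
            )
        spec_id = block.get("id") or block.get("image") or f"specimen_{i + 1}"
        if spec_id in seen_ids:
            raise TPSFormatError(f"{path}: duplicate specimen id {spec_id!r}")
        seen_ids.add(spec_id)
        scale = float(block.get("scale", 1.0))
        coords = np.asarray(block["coords"], dtype=float) * scale
        if flip_y:
            coords[:, 1] = -coords[:, 1]
        if meta is None or spec_id not in meta:
            unmatched.append(spec_id)
            continue
        m = meta[spec_id]
        specimens.append(
            Specimen(
                id=spec_id,
                stage=m["stage"],
                genotype=m["genotype"],
                sex=m.get("sex", "unknown"),
                landmarks=coords,
                scale=scale,
                scheme=scheme,
            )
        )
    if unmatched:
        raise MetadataError(
            f"no metadata for specimen ids: {', '.join(sorted(unmatched))}"
        )
    return specimens


def _coerce_metadata(metadata) -> Mapping[str, Mapping[str, str]] | None:
    if metadata is None:
        return None
    if isinstance(metadata, (str, Path)):
        metadata = pd.read_csv(metadata, dtype=str)
    if isinstance(metadata, pd.DataFrame):
        required = {"id", "stage", "genotype"}
        missing = required - set(metadata.columns)
        if missing:
            raise MetadataError(f"metadata is missing columns: {sorted(missing)}")
        records = {}
        for row in metadata.to_dict("records"):
            rid = str(row["id"])
            if rid in records:
                raise MetadataError(f"duplicate metadata id {rid!r}")
            records[rid] = {
                "stage": row["stage"],
                "genotype": row["genotype"],
                "sex": row.get("sex", "unknown") or "unknown",
            }
        return records
    return metadata


def write_tps(specimens: Iterable[Specimen], path: str | Path) -> None:
    """Write specimens as TPS blocks (coordinates in mm, SCALE=1)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for spec in specimens:
            fh.write(f"LM={spec.scheme.n_landmarks}\n")
            for x, y in spec.landmarks:
                fh.write(f"{x:.12g} {y:.12g}\n")
            fh.write(f"ID={spec.id}\n")
    logger.debug("wrote TPS file %s", path)


def write_metadata(specimens: Iterable[Specimen], path: str | Path) -> None:
    rows = [
        {"id": s.id, "stage": s.stage, "genotype": s.genotype, "sex": s.sex}
        for s in specimens
    ]
    pd.DataFrame(rows, columns=["id", "stage", "genotype", "sex"]).to_csv(path, index=False)


def write_table(records: Sequence[Mapping] | pd.DataFrame, path: str | Path,
                columns: Sequence[str] | None = None,
                header_comment: str | None = None) -> None:
    """Write records as UTF-8 CSV ('.' decimal separator, empty for missing).

    ``header_comment`` is emitted as a leading ``#`` line (used by the
    pipeline to stamp outputs with the config hash); :func:`read_table`
    skips such lines.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=columns)
        if columns is not None:
            df = df.reindex(columns=columns)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Wide-format landmark CSV (one row per specimen: id, stage, genotype, sex,
# x1..y17).  Configurable column naming for third-party exports.
# ---------------------------------------------------------------------------

def _coord_columns(n: int, x_fmt: str = "x{}", y_fmt: str = "y{}") -> list[str]:
    cols: list[str] = []
    for k in range(1, n + 1):
        cols.extend([x_fmt.format(k), y_fmt.format(k)])
    return cols


def write_landmarks_csv(specimens: Iterable[Specimen], path: str | Path) -> None:
    rows = []
    for s in specimens:
        row: dict = {"id": s.id, "stage": s.stage, "genotype": s.genotype, "sex": s.sex}
        flat = s.landmarks.reshape(-1)
        for col, v in zip(_coord_columns(s.scheme.n_landmarks), flat):
            row[col] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(
    path: str | Path,
    scheme: LandmarkScheme = DEFAULT_SCHEME,
    x_fmt: str = "x{}",
    y_fmt: str = "y{}",
    id_col: str = "id",
    stage_col: str = "stage",
    genotype_col: str = "genotype",
    sex_col: str = "sex",
) -> list[Specimen]:
    """Read a wide landmark table; column layout is configurable."""
    df = pd.read_csv(path)
    cols = _coord_columns(scheme.n_landmarks, x_fmt, y_fmt)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing coordinate columns {missing[:4]}...")
    specimens = []
    for row in df.to_dict("records"):
        coords = np.array([row[c] for c in cols], dtype=float).reshape(-1, 2)
        specimens.append(
            Specimen(
                id=str(row[id_col]),
                stage=str(row[stage_col]),
                genotype=str(row[genotype_col]),
                sex=str(row.get(sex_col, "unknown")),
                landmarks=coords,
                scheme=scheme,
            )
        )
    ids = [s.id for s in specimens]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate specimen ids")
    return specimens
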