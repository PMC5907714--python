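"""Reading and writing landmark data.

Two on-disk formats are supported: the plain-text TPS dialect written by the
tpsDig digitising software (records of ``LM=<n>`` followed by ``n`` coordinate
lines and optional ``IMAGE=``, ``ID=``, ``SCALE=`` keys) and wide tabular files
(CSV/TSV/XLSX) with one specimen per row.  Specimen identity strings follow the
museum-collection convention ``museum_accession_group_breed_morphotype`` and are
decoded against the code tables below.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "SpecimenMetadata",
    "Dataset",
    "parse_id_string",
    "read_tps",
    "write_tps",
    "read_landmark_table",
    "write_landmark_table",
    "MUSEUM_CODES",
    "GROUP_CODES",
    "BREED_CODES",
    "MORPHOTYPE_CODES",
]

MUSEUM_CODES = {
    "A": "Argentina",
    "B": "Berlin",
    "H": "Halle",
    "K": "Kiel",
    "V": "Vienna",
}

GROUP_CODES = {
    "H": "horse",
    "D": "donkey",
    "P": "Przewalski's",
    "Z": "zebra",
}

# Breed codes; "aaa" marks a specimen that is not a domesticated horse.
BREED_CODES = {
    "aaa": "not a domesticated horse",
    "ahb": "Ancient Breed (Roman period)",
    "ano": "Anglo-Norman",
    "arb": "Arab",
    "bif": "Birkenfelder",
    "blg": "Belgian Draft",
    "bos": "Bosnian Pony",
    "cds": "Clydesdale",
    "exm": "Exmoor Pony",
    "fab": "Falabella",
    "gbh": "Galician Farm Horse",
    "grb": "Grisons (Graubündner)",
    "grp": "German Riding Pony",
    "han": "Hannoverian",
    "hny": "Hackney",
    "hol": "Holstein",
    "hun": "Hungarian",
    "huz": "Huzule",
    "ice": "Icelandic Horse",
    "ind": "Indian Pony",
    "kdr": "Kladrubian",
    "kon": "Konik",
    "kos": "Kosarian",
    "lpz": "Lipizzan",
    "mon": "Mongolian",
    "nor": "Norik",
    "odb": "Oldenburgian",
    "piz": "Pinzgau",
    "pll": "Polish Farm Horse",
    "scp": "Scottish Pony",
    "ses": "Seneca Sarajevo",
    "she": "Shetland Pony",
    "shi": "Shire",
    "stm": "Styrian",
    "suf": "Suffolk",
    "tbh": "English Thoroughbred",
    "tog": "Togo Pony",
    "trk": "Trakehner",
    "wel": "Welsh",
}

MORPHOTYPE_CODES = {
    "A": "not a domesticated horse",
    "W": "Medium horse",
    "F": "Light horse",
    "C": "Draft horse",
    "P": "Pony",
}


class LandmarkFormatError(ValueError):
    """Raised when a landmark file or identifier cannot be parsed."""


@dataclass
class LandmarkConfiguration:
    """One specimen's k x m landmark coordinate matrix plus identity."""

    specimen_id: str
    coords: np.ndarray
    view_tag: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError(
                f"{self.specimen_id}: coords must be k x m with m in (2, 3), "
                f"got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 3:
            raise ValueError(f"{self.specimen_id}: need at least 3 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"{self.specimen_id}: configuration contains missing or "
                "non-finite coordinates; incomplete specimens are not supported"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def m(self) -> int:
        return self.coords.shape[1]


@dataclass
class SpecimenMetadata:
    """Decoded specimen identity fields."""

    museum: str
    accession: str
    group: str
    breed: str
    morphotype: str

    @property
    def museum_label(self) -> str:
        return MUSEUM_CODES[self.museum]

    @property
    def group_label(self) -> str:
        return GROUP_CODES[self.group]

    @property
    def breed_label(self) -> str:
        return BREED_CODES[self.breed]

    @property
    def morphotype_label(self) -> str:
        return MORPHOTYPE_CODES[self.morphotype]

    @property
    def id_string(self) -> str:
        return "_".join(
            [self.museum, self.accession, self.group, self.breed, self.morphotype]
        )


@dataclass
class Dataset:
    """An ordered collection of same-shape landmark configurations.

    Group membership comes from decoded metadata when present, or from an
    explicit ``group_labels`` array (e.g. for simulated data whose groups are
    not museum codes).
    """

    configurations: list[LandmarkConfiguration]
    metadata: list[SpecimenMetadata] | None = None
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels)
            if len(self.group_labels) != len(self.configurations):
                raise ValueError("group_labels length does not match configurations")
        if self.configurations:
            k, m = self.configurations[0].k, self.configurations[0].m
            for c in self.configurations:
                if (c.k, c.m) != (k, m):
                    raise ValueError(
                        f"inconsistent landmark shape: {c.specimen_id} has "
                        f"({c.k}, {c.m}), expected ({k}, {m})"
                    )
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            raise ValueError("specimen ids are not unique")
        if self.metadata is not None and len(self.metadata) != len(self.configurations):
            raise ValueError("metadata length does not match configurations")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def m(self) -> int:
        return self.configurations[0].m

    @property
    def ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def coords(self) -> np.ndarray:
        """n x k x m array of raw coordinates."""
        return np.stack([c.coords for c in self.configurations])

    @property
    def groups(self) -> np.ndarray:
        """Group label per specimen (from metadata or explicit labels)."""
        if self.group_labels is not None:
            return self.group_labels
        if self.metadata is None:
            raise ValueError("dataset carries neither metadata nor group labels")
        return np.array([md.group for md in self.metadata])

    def subset(self, indices: Sequence[int]) -> "Dataset":
        meta = None if self.metadata is None else [self.metadata[i] for i in indices]
        labels = None if self.group_labels is None else self.group_labels[list(indices)]
        return Dataset([self.configurations[i] for i in indices], meta, labels)

    def metadata_frame(self) -> pd.DataFrame:
        if self.metadata is None:
            raise ValueError("dataset carries no metadata")
        return pd.DataFrame(
            {
                "specimen_id": self.ids,
                "museum": [md.museum for md in self.metadata],
                "accession": [md.accession for md in self.metadata],
                "group": [md.group for md in self.metadata],
                "breed": [md.breed for md in self.metadata],
                "morphotype": [md.morphotype for md in self.metadata],
            }
        )


def parse_id_string(id_string: str, delimiter: str = "_") -> SpecimenMetadata:
    """Decode a ``museum_accession_group_breed_morphotype`` identity string.

    The accession may itself contain the delimiter; the museum code is the
    first field and the last three fields are group, breed and morphotype.
    """
    parts = id_string.split(delimiter)
    if len(parts) < 5:
        raise LandmarkFormatError(
            f"ID string {id_string!r} has {len(parts)} fields, expected 5 "
            "(museum, accession, group, breed, morphotype)"
        )
    museum, accession = parts[0], delimiter.join(parts[1:-3])
    group, breed, morphotype = parts[-3], parts[-2], parts[-1]
    for value, table, name in [
        (museum, MUSEUM_CODES, "museum"),
        (group, GROUP_CODES, "group"),
        (breed, BREED_CODES, "breed"),
        (morphotype, MORPHOTYPE_CODES, "morphotype"),
    ]:
        if value not in table:
            raise LandmarkFormatError(
                f"unknown {name} code {value!r} in {id_string!r}; "
                f"valid codes: {sorted(table)}"
            )
    md = SpecimenMetadata(museum, accession, group, breed, morphotype)
    if (md.group == "H") != (md.breed != "aaa"):
        raise LandmarkFormatError(
            f"{id_string!r}: breed {breed!r} inconsistent with group {group!r} "
            "(domesticated horses carry a breed code, other groups 'aaa')"
        )
    if (md.morphotype == "A") != (md.group != "H"):
        raise LandmarkFormatError(
            f"{id_string!r}: morphotype {morphotype!r} inconsistent with group "
            f"{group!r}"
        )
    return md


_TPS_KEY = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def read_tps(path: str | Path, parse_metadata: bool = False,
             id_delimiter: str = "_") -> Dataset:
    """Read a tpsDig-dialect landmark file.

    Each record starts with ``LM=<n>`` followed by ``n`` whitespace-separated
    coordinate lines and optional ``IMAGE=``, ``ID=`` and ``SCALE=`` lines.
    Coordinates are multiplied by the scale factor when one is present; the
    stored y-axis orientation is preserved.  An empty file yields an empty
    dataset.
    """
    lines = Path(path).read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i, record_index = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _TPS_KEY.match(line)
        if m is None or m.group(1).upper() != "LM":
            raise LandmarkFormatError(
                f"record {record_index}: expected 'LM=<n>', got {line!r}"
            )
        try:
            n_lm = int(m.group(2))
        except ValueError as exc:
            raise LandmarkFormatError(
                f"record {record_index}: bad landmark count {m.group(2)!r}"
            ) from exc
        i += 1
        coords = []
        while i < len(lines) and len(coords) < n_lm:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if _TPS_KEY.match(row) and not row[0].isdigit() and row[0] not in "+-.":
                break
            values = row.split()
            try:
                coords.append([float(v) for v in values])
            except ValueError as exc:
                raise LandmarkFormatError(
                    f"record {record_index}: bad coordinate line {row!r}"
                ) from exc
            i += 1
        if len(coords) != n_lm:
            raise LandmarkFormatError(
                f"record {record_index}: LM={n_lm} but only {len(coords)} "
                "coordinate lines found"
            )
        image = None
        spec_id = None
        scale = 1.0
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            m = _TPS_KEY.match(row)
            if m is None:
                raise LandmarkFormatError(
                    f"record {record_index}: unexpected line {row!r}"
                )
            key = m.group(1).upper()
            if key == "LM":
                break
            if key == "IMAGE":
                image = m.group(2)
            elif key == "ID":
                spec_id = m.group(2)
            elif key == "SCALE":
                scale = float(m.group(2))
            i += 1
        if spec_id is None:
            spec_id = image if image is not None else f"record_{record_index}"
        arr = np.asarray(coords, dtype=float) * scale
        configs.append(LandmarkConfiguration(spec_id, arr))
        record_index += 1
    metadata = None
    if parse_metadata:
        metadata = [parse_id_string(c.specimen_id, id_delimiter) for c in configs]
    return Dataset(configs, metadata)


def write_tps(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset in tpsDig dialect (full float precision, scale 1)."""
    out: list[str] = []
    for c in dataset.configurations:
        out.append(f"LM={c.k}")
        for row in c.coords:
            out.append(" ".join(repr(float(v)) for v in row))
        out.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


def read_landmark_table(
    path: str | Path,
    dims: int,
    id_column: str | int = 0,
    layout: str = "landmark-major",
    parse_metadata: bool = True,
    id_delimiter: str = "_",
    sep: str | None = None,
) -> Dataset:
    """Read a wide tabular landmark file (one specimen per row).

    Parameters
    ----------
    dims : number of coordinate axes per landmark (2 or 3).
    layout : ``"landmark-major"`` for columns x1,y1,z1,x2,... or
        ``"axis-major"`` for x1..xk,y1..yk,z1..zk.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if isinstance(id_column, int):
        id_column = df.columns[id_column]
    ids = df[id_column].astype(str).tolist()
    values = df.drop(columns=[id_column]).to_numpy(dtype=float)
    if values.shape[1] % dims != 0:
        raise LandmarkFormatError(
            f"{values.shape[1]} coordinate columns not divisible by dims={dims}"
        )
    k = values.shape[1] // dims
    configs = []
    for spec_id, row in zip(ids, values):
        if not np.all(np.isfinite(row)):
            raise LandmarkFormatError(f"specimen {spec_id}: missing coordinates")
        if layout == "landmark-major":
            coords = row.reshape(k, dims)
        elif layout == "axis-major":
            coords = row.reshape(dims, k).T
        else:
            raise ValueError(f"unknown layout {layout!r}")
        configs.append(LandmarkConfiguration(spec_id, coords))
    metadata = None
    if parse_metadata:
        metadata = [parse_id_string(s, id_delimiter) for s in ids]
    return Dataset(configs, metadata)


def write_landmark_table(
    dataset: Dataset, path: str | Path, layout: str = "landmark-major"
) -> None:
    """Write a dataset as a wide CSV (inverse of :func:`read_landmark_table`)."""
    k, m = dataset.k, dataset.m
    axes = "xyz"[:m]
    if layout == "landmark-major":
        cols = [f"{ax}{i + 1}" for i in range(k) for ax in axes]
        data = dataset.coords.reshape(len(dataset), k * m)
    elif layout == "axis-major":
        cols = [f"{ax}{i + 1}" for ax in axes for i in range(k)]
        data = dataset.coords.transpose(0, 2, 1).reshape(len(dataset), k * m)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "ID_String", dataset.ids)
    df.to_csv(path, index=False)
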