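"""Alignment and sample-metadata input/output.

The analyses in this package operate on pre-aligned, equal-length
mitochondrial sequence matrices (no indels are expected in the target
marker) paired with per-sample metadata: a population label, a clade
assignment, and decimal-degree coordinates.  This module reads and
validates both, and handles serialization of labeled distance matrices.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Nexus import Nexus

__all__ = [
    "Alignment",
    "SampleTable",
    "AlignmentError",
    "read_alignment",
    "write_alignment",
    "read_sample_table",
    "write_sample_table",
    "read_distance_matrix",
    "write_distance_matrix",
]

# IUPAC nucleotide codes, plus gap and missing symbols.
IUPAC_CODES = set("ACGTRYSWKMBDHVN") | {"-", "?"}

#: Map from IUPAC code to the set of unambiguous bases it may represent.
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"}, "?": {"A", "C", "G", "T"}, "-": set(),
}


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate ids, bad symbols)."""


@dataclass
class Alignment:
    """Equal-length nucleotide matrix keyed by sample id.

    Characters are stored upper-cased as a 2-D numpy array of single
    characters (one row per sample, one column per aligned site).
    """

    sample_ids: list[str]
    characters: np.ndarray  # shape (n_samples, n_sites), dtype '<U1'

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.characters = np.asarray(self.characters, dtype="<U1")
        if self.characters.ndim != 2:
            raise AlignmentError("character matrix must be 2-D")
        if len(self.sample_ids) != self.characters.shape[0]:
            raise AlignmentError(
                f"{len(self.sample_ids)} ids for {self.characters.shape[0]} rows"
            )
        if any(not s for s in self.sample_ids):
            raise AlignmentError("empty sample id")
        dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
        if dupes:
            raise AlignmentError(f"duplicate sample ids: {sorted(dupes)}")
        bad = set(np.unique(self.characters)) - IUPAC_CODES
        if bad:
            raise AlignmentError(f"non-IUPAC characters in alignment: {sorted(bad)}")

    @classmethod
    def from_sequences(cls, ids: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        seqs = [normalize_sequence(s) for s in seqs]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            by_len: dict[int, list[str]] = {}
            for i, s in zip(ids, seqs):
                by_len.setdefault(len(s), []).append(str(i))
            raise AlignmentError(f"ragged alignment; lengths by id: {by_len}")
        if seqs:
            mat = np.array([list(s) for s in seqs], dtype="<U1")
        else:
            mat = np.empty((0, 0), dtype="<U1")
        return cls(list(ids), mat)

    @property
    def n_samples(self) -> int:
        return self.characters.shape[0]

    @property
    def n_sites(self) -> int:
        return self.characters.shape[1]

    def sequence(self, sample_id: str) -> str:
        return "".join(self.characters[self._index(sample_id)])

    def _index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample id not in alignment: {sample_id!r}") from None

    def subset(self, ids: Iterable[str]) -> "Alignment":
        ids = list(ids)
        rows = [self._index(s) for s in ids]
        return Alignment(ids, self.characters[rows])

    def drop(self, ids: Iterable[str]) -> "Alignment":
        """Return an alignment without the named samples (missing ids ignored)."""
        drop = set(ids)
        keep = [s for s in self.sample_ids if s not in drop]
        return self.subset(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.characters.shape == other.characters.shape
            and bool(np.all(self.characters == other.characters))
        )


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and map RNA 'U' to 'T'."""
    return str(seq).upper().replace("U", "T")


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"nexus", "fasta"}:
            raise ValueError(f"unsupported alignment format: {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".nex", ".nexus", ".nxs"}:
        return "nexus"
    if suffix in {".fa", ".fas", ".fasta", ".fna"}:
        return "fasta"
    with open(path) as fh:
        head = fh.read(64).lstrip()
    return "nexus" if head.upper().startswith("#NEXUS") else "fasta"


def read_alignment(path: str | Path, format: str | None = None) -> Alignment:
    """Read a NEXUS or FASTA alignment, preserving sample order.

    Sequences are upper-cased and 'U' is mapped to 'T'.  Ragged rows and
    duplicate ids raise :class:`AlignmentError` naming the offenders.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    ids: list[str] = []
    seqs: list[str] = []
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
    else:
        nex = Nexus.Nexus(str(path))
        for name in nex.taxlabels if nex.taxlabels else list(nex.matrix):
            ids.append(str(name))
            seqs.append(str(nex.matrix[name]))
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise AlignmentError(f"duplicate sample ids in {path.name}: {dupes}")
    return Alignment.from_sequences(ids, seqs)


def write_alignment(alignment: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment as FASTA or a simple non-interleaved NEXUS DATA block."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "fasta":
        with open(path, "w") as fh:
            for sid in alignment.sample_ids:
                fh.write(f">{sid}\n{alignment.sequence(sid)}\n")
    elif fmt == "nexus":
        pad = max((len(s) for s in alignment.sample_ids), default=1) + 2
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(
                f"  DIMENSIONS NTAX={alignment.n_samples} NCHAR={alignment.n_sites};\n"
            )
            fh.write(
                "  FORMAT DATATYPE=DNA MISSING=? GAP=- INTERLEAVE=NO;\n  MATRIX\n"
            )
            for sid in alignment.sample_ids:
                safe = f"'{sid}'" if re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]", sid) else sid
                fh.write(f"  {safe.ljust(pad)}{alignment.sequence(sid)}\n")
            fh.write("  ;\nEND;\n")
    else:
        raise ValueError(f"unsupported alignment format: {format!r}")


# ---------------------------------------------------------------------------
# Sample metadata

_COLUMN_ALIASES = {
    "sample_id": {"sample_id", "id", "sample", "name"},
    "population": {"population", "population_label", "pop", "#"},
    "clade": {"clade", "clade_label"},
    "latitude": {"latitude", "lat", "lat_n"},
    "longitude": {"longitude", "lon", "long", "lng"},
    "taxon": {"taxon", "species"},
    "introduced_candidate": {"introduced_candidate", "introduced"},
}

REQUIRED_COLUMNS = ("sample_id", "population", "clade", "latitude", "longitude")


@dataclass
class SampleTable:
    """Per-sample population, clade, and coordinate metadata.

    Thin wrapper around a pandas DataFrame with canonical columns
    ``sample_id, population, clade, latitude, longitude, taxon,
    introduced_candidate``.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table missing required columns: {missing}")
        if "taxon" not in df.columns:
            df["taxon"] = ""
        if "introduced_candidate" not in df.columns:
            df["introduced_candidate"] = False
        for col in ("sample_id", "population", "clade", "taxon"):
            df[col] = df[col].astype(str)
        for col in ("latitude", "longitude"):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"non-numeric {col} in sample table: {exc}") from None
        df["introduced_candidate"] = df["introduced_candidate"].map(
            lambda v: str(v).strip().lower() in {"true", "1", "yes", "*"}
        )
        bad_lat = df[(df.latitude < -90) | (df.latitude > 90)]
        if len(bad_lat):
            raise ValueError(
                f"latitude out of [-90, 90] for rows: {bad_lat.sample_id.tolist()}"
            )
        bad_lon = df[(df.longitude < -180) | (df.longitude > 180)]
        if len(bad_lon):
            raise ValueError(
                f"longitude out of [-180, 180] for rows: {bad_lon.sample_id.tolist()}"
            )
        dupes = df.sample_id[df.sample_id.duplicated()].tolist()
        if dupes:
            raise ValueError(f"duplicate sample ids in table: {dupes}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df.sample_id.tolist()

    def row(self, sample_id: str) -> pd.Series:
        hit = self.df[self.df.sample_id == sample_id]
        if hit.empty:
            raise KeyError(f"sample id not in table: {sample_id!r}")
        return hit.iloc[0]

    def coordinates(self, sample_id: str) -> tuple[float, float]:
        r = self.row(sample_id)
        return float(r.latitude), float(r.longitude)

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        ids = set(sample_ids)
        return SampleTable(self.df[self.df.sample_id.isin(ids)])

    def subset_clades(self, clades: Iterable[str]) -> "SampleTable":
        clades = {str(c) for c in clades}
        return SampleTable(self.df[self.df.clade.isin(clades)])

    def drop_populations(self, populations: Iterable[str]) -> "SampleTable":
        pops = {str(p) for p in populations}
        return SampleTable(self.df[~self.df.population.isin(pops)])

    def require_alignment(self, alignment: Alignment) -> None:
        """Fail loudly when the alignment contains ids this table does not."""
        missing = sorted(set(alignment.sample_ids) - set(self.sample_ids))
        if missing:
            raise ValueError(
                f"alignment ids absent from sample table: {missing}"
            )

    def population_coordinates(self) -> pd.DataFrame:
        """One row per population with its (mean) coordinates."""
        return (
            self.df.groupby("population", sort=False)[["latitude", "longitude"]]
            .mean()
            .reset_index()
        )


def read_sample_table(path: str | Path) -> SampleTable:
    """Read delimiter-separated sample metadata (comma or tab, auto-detected)."""
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    renames = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for col in raw.columns:
            if col.strip().lower() in aliases and canon not in renames.values():
                renames[col] = canon
    df = raw.rename(columns=renames)
    return SampleTable(df)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Distance matrices

UNDEFINED_TOKEN = "NA"


def write_distance_matrix(matrix, path: str | Path, format: str = "csv") -> None:
    """Write a labeled distance matrix.

    ``csv`` is a square delimiter-separated layout with ``#`` header
    comments recording the units and the sentinel used for undefined
    cells; ``phylip`` is the square PHYLIP layout (no comments, same
    sentinel).
    """
    path = Path(path)
    fmt = format.lower()
    vals = matrix.values
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# units={matrix.units}\n")
            fh.write(f"# undefined cells written as {UNDEFINED_TOKEN}\n")
            fh.write("," + ",".join(matrix.labels) + "\n")
            for i, lab in enumerate(matrix.labels):
                cells = [
                    UNDEFINED_TOKEN if np.isnan(v) else repr(float(v))
                    for v in vals[i]
                ]
                fh.write(lab + "," + ",".join(cells) + "\n")
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(matrix.labels)}\n")
            for i, lab in enumerate(matrix.labels):
                cells = [
                    UNDEFINED_TOKEN if np.isnan(v) else repr(float(v))
                    for v in vals[i]
                ]
                fh.write(lab.ljust(12) + " " + " ".join(cells) + "\n")
    else:
        raise ValueError(f"unsupported distance-matrix format: {format!r}")


def read_distance_matrix(path: str | Path, format: str | None = None, units: str | None = None):
    """Read a distance matrix written by :func:`write_distance_matrix`."""
    from .distances import DistanceMatrix  # local import avoids a cycle

    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header_units = units
    body = []
    for ln in lines:
        if ln.startswith("#"):
            m = re.search(r"units=(\S+)", ln)
            if m and units is None:
                header_units = m.group(1)
            continue
        body.append(ln)
    if format is None:
        format = "phylip" if re.fullmatch(r"\d+", body[0].strip()) else "csv"
    if format == "phylip":
        n = int(body[0])
        labels, rows = [], []
        for ln in body[1 : n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([np.nan if p == UNDEFINED_TOKEN else float(p) for p in parts[1:]])
    else:
        frame = pd.read_csv(io.StringIO("\n".join(body)), index_col=0)
        labels = [str(c) for c in frame.columns]
        rows = [
            [np.nan if str(v) == UNDEFINED_TOKEN else float(v) for v in frame.loc[idx]]
            for idx in frame.index
        ]
    values = np.array(rows, dtype=float)
    return DistanceMatrix(labels, values, units=header_units or "substitutions/site")
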