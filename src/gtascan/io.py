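"""Record types and readers/writers for the package's external formats.

Formats handled here:

* protein FASTA, with an optional structured header convention
  ``>id|genome|replicon|start|end|strand`` carrying genomic coordinates
  (1-based, inclusive, GenBank convention);
* BED sidecar files for coordinates (0-based half-open; converted on read);
* square, labelled, tab-separated pairwise distance matrices;
* tab-separated prediction and ANI tables.

Sequences are cleaned to the 20-letter amino-acid alphabet on read:
ambiguity codes (B, J, O, U, X, Z), stop symbols and gap characters are
removed (not recoded) because every downstream feature is defined only over
the canonical residues; the number of removed characters is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

#: class labels: GTA is -1, virus is +1
GTA_LABEL = -1
VIRUS_LABEL = +1


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence, optionally located on a replicon.

    Coordinates are 1-based and inclusive on both ends.
    """

    id: str
    sequence: str
    genome_id: str | None = None
    replicon_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-canonical residues {sorted(bad)}"
            )
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"record {self.id!r}: start > end")
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValueError(f"record {self.id!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_coordinates(self) -> bool:
        return (
            self.replicon_id is not None
            and self.start is not None
            and self.end is not None
        )


@dataclass
class DistanceMatrix:
    """Symmetric, non-negative pairwise distance matrix with row/column ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in distance matrix")
        if np.any(self.values < 0):
            raise ValueError("negative distances")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric within 1e-9")
        np.fill_diagonal(self.values, 0.0)
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class LabeledTrainingSet:
    """Training records with class labels (GTA = -1, virus = +1) and weights."""

    records: list[SequenceRecord]
    labels: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.weights is None:
            self.weights = np.ones(len(self.records))
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.records) == len(self.labels) == len(self.weights)):
            raise ValueError("records, labels and weights must be aligned")
        if not set(np.unique(self.labels)) <= {GTA_LABEL, VIRUS_LABEL}:
            raise ValueError("labels must be -1 (GTA) or +1 (virus)")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, indices: Sequence[int]) -> "LabeledTrainingSet":
        idx = list(indices)
        return LabeledTrainingSet(
            [self.records[i] for i in idx], self.labels[idx], self.weights[idx]
        )

    def require_both_classes(self) -> None:
        if GTA_LABEL not in self.labels or VIRUS_LABEL not in self.labels:
            raise ValueError("training set must contain both classes")


def make_training_set(
    gta: Iterable[SequenceRecord], virus: Iterable[SequenceRecord]
) -> LabeledTrainingSet:
    """Combine GTA (-1) and virus (+1) records into one labelled set."""
    gta = list(gta)
    virus = list(virus)
    records = gta + virus
    labels = np.array([GTA_LABEL] * len(gta) + [VIRUS_LABEL] * len(virus))
    return LabeledTrainingSet(records, labels)


def _clean_sequence(raw: str) -> tuple[str, int]:
    seq = raw.upper()
    kept = [c for c in seq if c in _AA_SET]
    return "".join(kept), len(seq) - len(kept)


def _parse_header(header: str) -> dict:
    """Parse the ``id|genome|replicon|start|end|strand`` header convention.

    Headers without the full six pipe-separated fields yield only an id
    (the first whitespace-delimited token).
    """
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) == 6:
        sid, genome, replicon, start, end, strand = parts
        try:
            return {
                "id": sid,
                "genome_id": genome or None,
                "replicon_id": replicon or None,
                "start": int(start),
                "end": int(end),
                "strand": strand if strand in {"+", "-"} else None,
            }
        except ValueError:
            pass
    return {"id": token}


def read_protein_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein sequences, cleaning them to the canonical alphabet.

    Raises on an empty file, a duplicate id, or a record whose sequence is
    empty after removing non-canonical characters.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    n_removed_total = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        fields = _parse_header(entry.description)
        sid = fields["id"]
        if sid in seen:
            raise ValueError(f"{path}: duplicate sequence id {sid!r}")
        seen.add(sid)
        cleaned, n_removed = _clean_sequence(str(entry.seq))
        n_removed_total += n_removed
        if not cleaned:
            raise ValueError(
                f"{path}: record {sid!r} empty after removing non-canonical residues"
            )
        records.append(SequenceRecord(sequence=cleaned, **fields))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if n_removed_total:
        logger.info(
            "%s: removed %d non-canonical characters across %d records",
            path,
            n_removed_total,
            len(records),
        )
    return records


def write_protein_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records, emitting the structured header when coordinates exist."""
    bio_records = []
    for r in records:
        if r.has_coordinates:
            header = "|".join(
                [
                    r.id,
                    r.genome_id or "",
                    r.replicon_id or "",
                    str(r.start),
                    str(r.end),
                    r.strand or "",
                ]
            )
        else:
            header = r.id
        bio_records.append(
            _BioSeqRecord(Seq(r.sequence), id=header, description="")
        )
    SeqIO.write(bio_records, str(path), "fasta")


def apply_bed_coordinates(
    records: Sequence[SequenceRecord],
    path: str | Path,
    genome_id: str | None = None,
) -> list[SequenceRecord]:
    """Attach coordinates from a BED sidecar to records, matched by BED name.

    BED is 0-based half-open; coordinates are converted to 1-based inclusive.
    The BED ``chrom`` column is taken as the replicon id. Records without a
    BED line are returned unchanged.
    """
    path = Path(path)
    coords: dict[str, dict] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{line_no}: BED line needs >= 4 columns")
            chrom, start, end, name = parts[:4]
            strand = parts[5] if len(parts) >= 6 and parts[5] in {"+", "-"} else None
            coords[name] = {
                "replicon_id": chrom,
                "start": int(start) + 1,
                "end": int(end),
                "strand": strand,
            }
    out = []
    for r in records:
        if r.id in coords:
            c = coords[r.id]
            out.append(
                replace(
                    r,
                    genome_id=r.genome_id or genome_id,
                    replicon_id=c["replicon_id"],
                    start=c["start"],
                    end=c["end"],
                    strand=c["strand"],
                )
            )
        else:
            out.append(r)
    return out


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square labelled tab-separated distance matrix.

    Row and column labels must agree; asymmetry above 1e-6 is an error and
    smaller asymmetry is averaged away.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({df.shape})")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row labels do not match column labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix") from exc
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing value in matrix")
    asym = np.abs(values - values.T).max()
    if asym > 1e-6:
        raise ValueError(f"{path}: matrix asymmetric (max |d_ij - d_ji| = {asym:g})")
    values = (values + values.T) / 2.0
    return DistanceMatrix([str(s) for s in df.index], values)


def write_predictions(
    records: Sequence[SequenceRecord],
    scores: Sequence[float],
    labels: Sequence[str],
    path: str | Path,
    model_id: str = "model",
) -> None:
    """Write one tab-separated row per query: id, model, decision value, class."""
    if not (len(records) == len(scores) == len(labels)):
        raise ValueError("records, scores and labels must be aligned")
    with open(path, "w") as fh:
        fh.write("query_id\tmodel\tscore\tclass\n")
        for r, s, lab in zip(records, scores, labels):
            fh.write(f"{r.id}\t{model_id}\t{s:g}\t{lab}\n")


def read_ani_table(path: str | Path) -> pd.DataFrame:
    """Read a pairwise ANI table: genome_a, genome_b, ani (percent, 0-100).

    A header row is accepted and detected; missing pairs mean "below any
    threshold of interest".
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: ANI table needs 3 columns")
    df = df.iloc[:, :3]
    df.columns = ["genome_a", "genome_b", "ani"]
    first = str(df.iloc[0, 2])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:].reset_index(drop=True)
    df["ani"] = df["ani"].astype(float)
    if ((df["ani"] < 0) | (df["ani"] > 100)).any():
        raise ValueError(f"{path}: ANI values must lie in [0, 100]")
    return df
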