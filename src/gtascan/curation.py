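"""Training-set curation: deduplication, outlier removal, taxonomic weighting.

Pairwise phylogenetic distances are consumed, not computed: the canonical
pipeline estimates them externally from a multiple alignment under a
maximum-likelihood substitution model. ``p_distance_matrix`` offers an
alignment-free-of-tooling fallback (plain p-distance over user-supplied
aligned sequences) for testing only; it is not the canonical distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from gtascan.io import (
    GTA_LABEL,
    DistanceMatrix,
    LabeledTrainingSet,
    SequenceRecord,
)

logger = logging.getLogger(__name__)


@dataclass
class WeightingResult:
    """Partition of sequence ids into similarity groups with weights 1/|group|."""

    groups: list[list[str]]
    weights: dict[str, float]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def weight_vector(self, ids: list[str]) -> np.ndarray:
        return np.array([self.weights[s] for s in ids])


@dataclass
class OutlierRow:
    """Per-bacterial-homolog outlier diagnostics."""

    id: str
    mean_bacterial_distance: float
    nearest_viral_distance: float
    is_outlier: bool
    removed: bool


@dataclass
class OutlierReport:
    rows: list[OutlierRow]
    q1: float
    q3: float
    fence: float

    @property
    def removed_ids(self) -> list[str]:
        return [r.id for r in self.rows if r.removed]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "id\tmean_bacterial_distance\tnearest_viral_distance\t"
                "is_outlier\tremoved\n"
            )
            for r in self.rows:
                fh.write(
                    f"{r.id}\t{r.mean_bacterial_distance:g}\t"
                    f"{r.nearest_viral_distance:g}\t{int(r.is_outlier)}\t"
                    f"{int(r.removed)}\n"
                )


def deduplicate(tset: LabeledTrainingSet) -> LabeledTrainingSet:
    """Drop exact within-class duplicate sequences, keeping first occurrences.

    Identical sequences appearing in both classes are kept (deduplication is
    within-class) but the conflict is logged.
    """
    seen: dict[int, set[str]] = {}
    keep: list[int] = []
    for i, (rec, lab) in enumerate(zip(tset.records, tset.labels)):
        bucket = seen.setdefault(int(lab), set())
        if rec.sequence in bucket:
            continue
        bucket.add(rec.sequence)
        keep.append(i)
    cross = seen.get(GTA_LABEL, set()) & seen.get(-GTA_LABEL, set())
    if cross:
        logger.warning(
            "%d identical sequences occur in both classes; kept in both", len(cross)
        )
    if len(keep) < len(tset):
        logger.info("deduplication removed %d records", len(tset) - len(keep))
    return tset.subset(keep)


def filter_outliers(
    dist: DistanceMatrix, labels: dict[str, int]
) -> tuple[list[str], OutlierReport]:
    """Remove bacterial homologs that are both intra-class outliers and
    closer to the viral class than to their own.

    For each bacterial (GTA-class) id the mean distance ``o`` to all other
    bacterial ids is computed; ids with ``o`` above the Tukey fence
    Q3 + 1.5 (Q3 - Q1) of the ``o`` distribution are flagged, and a flagged
    id is removed iff ``o`` also exceeds its shortest distance to any viral
    id. Quartiles use linear interpolation between order statistics.

    Returns the kept bacterial ids (input order) and the full report.
    """
    bacterial = [s for s in dist.ids if labels.get(s) == GTA_LABEL]
    viral = [s for s in dist.ids if labels.get(s) == -GTA_LABEL]
    if len(bacterial) < 3:
        raise ValueError("need at least 3 bacterial sequences to define quartiles")
    missing = set(labels) - set(dist.ids)
    if missing:
        raise ValueError(f"ids missing from distance matrix: {sorted(missing)[:5]}")

    o = {
        b: float(np.mean([dist.get(b, other) for other in bacterial if other != b]))
        for b in bacterial
    }
    values = np.array([o[b] for b in bacterial])
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation (type 7)
    fence = q3 + 1.5 * (q3 - q1)

    rows = []
    kept = []
    for b in bacterial:
        nearest_viral = (
            min(dist.get(b, v) for v in viral) if viral else float("inf")
        )
        flagged = o[b] > fence
        removed = flagged and o[b] > nearest_viral
        rows.append(OutlierRow(b, o[b], nearest_viral, flagged, removed))
        if not removed:
            kept.append(b)
    report = OutlierReport(rows, float(q1), float(q3), float(fence))
    if report.removed_ids:
        logger.info("outlier filter removed %d bacterial homologs", len(report.removed_ids))
    return kept, report


def assign_weights(dist: DistanceMatrix, t: float) -> WeightingResult:
    """Group sequences by farthest-neighbor (complete-linkage) clustering at
    threshold ``t`` and weight each sequence by 1/|group|.

    Two clusters merge while their complete-linkage distance is strictly
    below ``t``, so ``t = 0`` leaves every sequence in its own group even in
    the presence of duplicates. Ids are processed in sorted order, making
    the output invariant to input order.
    """
    if t < 0:
        raise ValueError("threshold t must be non-negative")
    ids = list(dist.ids)
    n = len(ids)
    if n == 1 or t == 0:
        return WeightingResult(
            groups=[[s] for s in sorted(ids)], weights={s: 1.0 for s in ids}
        )

    order = sorted(range(n), key=lambda i: ids[i])
    sorted_ids = [ids[i] for i in order]
    sub = dist.values[np.ix_(order, order)]
    condensed = squareform(sub, checks=False)
    Z = linkage(condensed, method="complete")
    # cut so that merges with height < t are applied (strictly below t)
    cut = np.nextafter(t, -np.inf)
    assignment = fcluster(Z, t=cut, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for sid, c in zip(sorted_ids, assignment):
        clusters.setdefault(int(c), []).append(sid)
    groups = sorted((sorted(members) for members in clusters.values()), key=lambda g: g[0])
    weights = {s: 1.0 / len(g) for g in groups for s in g}
    return WeightingResult(groups=groups, weights=weights)


def p_distance_matrix(aligned: list[SequenceRecord]) -> DistanceMatrix:
    """Non-canonical fallback: p-distance over equal-length aligned sequences.

    For testing and exploration only — the canonical pipeline uses
    maximum-likelihood distances computed externally.
    """
    lengths = {len(r.sequence) for r in aligned}
    if len(lengths) != 1:
        raise ValueError("p-distance requires equal-length (aligned) sequences")
    ids = [r.id for r in aligned]
    arr = np.array([list(r.sequence) for r in aligned])
    n = len(aligned)
    values = np.zeros((n, n))
    for i in range(n):
        diff = (arr != arr[i]).mean(axis=1)
        values[i] = diff
    values = (values + values.T) / 2.0
    return DistanceMatrix(ids, values)
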