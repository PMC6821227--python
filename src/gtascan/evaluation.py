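"""Cross-validated grid search, accuracy scoring and parameter selection.

For each candidate grid point (feature combination, regularization C,
weighting threshold t) the classifier is assessed by stratified 5-fold
cross-validation repeated 10 times. Per class, the Average Accuracy Score
(AAS) is the mean over folds and repeats of correct/total within the class;
the Weighted Accuracy Score gives both classes equal influence,

    WAS = 100 * (0.5 * AAS_GTA + 0.5 * AAS_virus),

and the Matthews correlation coefficient is computed from confusion counts
pooled over all folds and repeats (GTA is the positive class for
bookkeeping; MCC itself is symmetric).

Taxonomic-bias weights are recomputed inside every training fold from the
distance matrix restricted to that fold's training members, so no
information about held-out sequences leaks into the weights.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from gtascan.curation import assign_weights
from gtascan.features import FeatureSpec, SequenceFeaturizer
from gtascan.io import GTA_LABEL, VIRUS_LABEL, DistanceMatrix, LabeledTrainingSet
from gtascan.svm import WeightedSVC

logger = logging.getLogger(__name__)

C_GRID = (0.01, 0.1, 1, 100, 10000)
T_GRID = (0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.1)
K_CHOICES = (None, 1, 2, 3, 4, 5, 6)
LAMBDA_CHOICES = (None, 3, 6)


@dataclass(frozen=True)
class GridPoint:
    """One candidate parameter set: feature combination x C x t."""

    kmer_k: int | None
    pseaac_lambda: int | None
    physchem: bool
    C: float
    t: float

    def __post_init__(self) -> None:
        if self.kmer_k not in K_CHOICES:
            raise ValueError(f"kmer_k {self.kmer_k} not in declared grid")
        if self.pseaac_lambda not in LAMBDA_CHOICES:
            raise ValueError(f"pseaac_lambda {self.pseaac_lambda} not in declared grid")
        if self.kmer_k is None and self.pseaac_lambda is None and not self.physchem:
            raise ValueError("grid point must activate at least one encoder")
        if self.C not in C_GRID:
            raise ValueError(f"C {self.C} not in declared grid")
        if self.t not in T_GRID:
            raise ValueError(f"t {self.t} not in declared grid")

    @property
    def feature_spec(self) -> FeatureSpec:
        return FeatureSpec(
            kmer_k=self.kmer_k, pseaac_lambda=self.pseaac_lambda, physchem=self.physchem
        )

    def sort_key(self) -> tuple:
        # None (no k-mer encoder) sorts before any k
        return (self.kmer_k if self.kmer_k is not None else 0, self.C, self.t)


@dataclass
class CVResult:
    """Cross-validation summary for one grid point."""

    grid_point: GridPoint
    aas_gta: float
    aas_virus: float
    mcc: float
    per_repeat: list[tuple[float, float]] = field(default_factory=list)
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # tp, tn, fp, fn

    @property
    def was(self) -> float:
        return 100.0 * (0.5 * self.aas_gta + 0.5 * self.aas_virus)


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is zero."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + tn + fp + fn == 0:
        raise ValueError("confusion matrix is empty")
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        logger.debug("MCC denominator has a zero factor; returning 0")
        return 0.0
    return (tp * tn - fp * fn) / denom


def kfold_split(
    labels: np.ndarray, k: int = 5, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Stratified k-fold partition of sample indices.

    Each class is shuffled and dealt round-robin, so fold sizes differ by at
    most one and every fold contains both classes whenever each class has at
    least k members.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = rng or np.random.default_rng()
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        for offset, i in enumerate(idx):
            folds[(start + offset) % k].append(int(i))
        # continue dealing where the previous class stopped, keeping overall
        # fold sizes within one of each other
        start = (start + len(idx)) % k
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(
    tset: LabeledTrainingSet,
    dist: DistanceMatrix | None,
    gp: GridPoint,
    repeats: int = 10,
    seed: int = 0,
    n_folds: int = 5,
) -> CVResult:
    """Repeated stratified k-fold cross-validation at one grid point.

    ``dist`` may be None only when ``gp.t == 0`` (no weighting); otherwise
    the matrix must cover every training id.
    """
    tset.require_both_classes()
    if gp.t > 0:
        if dist is None:
            raise ValueError("a distance matrix is required when t > 0")
        missing = set(tset.ids) - set(dist.ids)
        if missing:
            raise ValueError(f"ids missing from distance matrix: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    gta_accs: list[float] = []
    virus_accs: list[float] = []
    per_repeat: list[tuple[float, float]] = []
    tp = tn = fp = fn = 0

    for _ in range(repeats):
        folds = kfold_split(tset.labels, n_folds, rng)
        rep_gta: list[float] = []
        rep_virus: list[float] = []
        for f in range(n_folds):
            val_idx = folds[f]
            train_idx = np.concatenate([folds[g] for g in range(n_folds) if g != f])
            train = tset.subset(train_idx)
            val = tset.subset(val_idx)
            if GTA_LABEL not in train.labels or VIRUS_LABEL not in train.labels:
                logger.warning("training fold lost a class; skipping fold")
                continue

            if gp.t > 0:
                weighting = assign_weights(dist.submatrix(train.ids), gp.t)
                d = weighting.weight_vector(train.ids)
            else:
                d = np.ones(len(train))

            fz = SequenceFeaturizer(
                kmer_k=gp.kmer_k,
                pseaac_lambda=gp.pseaac_lambda,
                physchem=gp.physchem,
            )
            X_train = fz.fit_transform(train.records)
            X_val = fz.transform(val.records)
            model = WeightedSVC(C=gp.C).fit(X_train, train.labels, sample_weight=d)
            pred = model.predict(X_val)

            for cls, acc_list in ((GTA_LABEL, rep_gta), (VIRUS_LABEL, rep_virus)):
                mask = val.labels == cls
                if not mask.any():
                    logger.warning(
                        "validation fold has no class-%d members; accuracy undefined",
                        cls,
                    )
                    continue
                acc_list.append(float(np.mean(pred[mask] == cls)))
            tp += int(np.sum((val.labels == GTA_LABEL) & (pred == GTA_LABEL)))
            tn += int(np.sum((val.labels == VIRUS_LABEL) & (pred == VIRUS_LABEL)))
            fp += int(np.sum((val.labels == VIRUS_LABEL) & (pred == GTA_LABEL)))
            fn += int(np.sum((val.labels == GTA_LABEL) & (pred == VIRUS_LABEL)))
        gta_accs.extend(rep_gta)
        virus_accs.extend(rep_virus)
        per_repeat.append(
            (float(np.mean(rep_gta)) if rep_gta else float("nan"),
             float(np.mean(rep_virus)) if rep_virus else float("nan"))
        )

    return CVResult(
        grid_point=gp,
        aas_gta=float(np.mean(gta_accs)),
        aas_virus=float(np.mean(virus_accs)),
        mcc=mcc(tp, tn, fp, fn),
        per_repeat=per_repeat,
        confusion=(tp, tn, fp, fn),
    )


def enumerate_grid(
    C_values=C_GRID,
    t_values=T_GRID,
    k_values=K_CHOICES,
    lambda_values=LAMBDA_CHOICES,
    physchem_values=(False, True),
) -> list[GridPoint]:
    """All non-empty feature combinations crossed with the C and t grids.

    With the default grids this yields 41 feature combinations
    ((6+1)(2+1)(1+1) - 1) x 5 C x 7 t = 1,435 points.
    """
    points = []
    for k, lam, pc in itertools.product(k_values, lambda_values, physchem_values):
        if k is None and lam is None and not pc:
            continue
        for C, t in itertools.product(C_values, t_values):
            points.append(GridPoint(k, lam, pc, C, t))
    return points


def select_best(results: list[CVResult], tol: float = 1e-9) -> GridPoint:
    """Pick the optimal grid point by highest WAS with the tie-break cascade.

    Ties at the maximal WAS are resolved in priority order: (1) keep
    candidates whose k-mer size has the highest mean WAS over all evaluated
    grid points sharing that size; (2) drop candidates using PseAAC or
    physicochemical features unless that empties the set; (3) keep the C
    with the highest mean WAS among remaining candidates; (4) keep the t
    with the highest mean WAS among remaining candidates; any final tie is
    broken by the smallest (k, C, t), with "no k-mer" ordering first.
    """
    if not results:
        raise ValueError("no results to select from")
    best_was = max(r.was for r in results)
    cand = [r for r in results if r.was >= best_was - tol]

    if len(cand) > 1:
        # (1) best-performing k-mer size on average, over the full grid
        mean_by_k: dict[int | None, float] = {}
        for k in {r.grid_point.kmer_k for r in cand}:
            vals = [r.was for r in results if r.grid_point.kmer_k == k]
            mean_by_k[k] = float(np.mean(vals))
        top = max(mean_by_k.values())
        cand = [r for r in cand if mean_by_k[r.grid_point.kmer_k] >= top - tol]

    if len(cand) > 1:
        # (2) avoid PseAAC / physicochemical features when possible
        plain = [
            r
            for r in cand
            if r.grid_point.pseaac_lambda is None and not r.grid_point.physchem
        ]
        if plain:
            cand = plain

    if len(cand) > 1:
        # (3) C with the highest mean WAS among remaining candidates
        mean_by_C = {
            C: float(np.mean([r.was for r in cand if r.grid_point.C == C]))
            for C in {r.grid_point.C for r in cand}
        }
        top = max(mean_by_C.values())
        cand = [r for r in cand if mean_by_C[r.grid_point.C] >= top - tol]

    if len(cand) > 1:
        # (4) t with the highest mean WAS among remaining candidates
        mean_by_t = {
            t: float(np.mean([r.was for r in cand if r.grid_point.t == t]))
            for t in {r.grid_point.t for r in cand}
        }
        top = max(mean_by_t.values())
        cand = [r for r in cand if mean_by_t[r.grid_point.t] >= top - tol]

    if len(cand) > 1:
        logger.info("parameter tie among %d sets; using smallest (k, C, t)", len(cand))
    return min(cand, key=lambda r: r.grid_point.sort_key()).grid_point


def write_grid_report(results: list[CVResult], path) -> None:
    """One row per grid point: features, C, t, AAS per class, WAS, MCC."""
    with open(path, "w") as fh:
        fh.write("kmer_k\tpseaac_lambda\tphyschem\tC\tt\taas_gta\taas_virus\twas\tmcc\n")
        for r in results:
            gp = r.grid_point
            fh.write(
                f"{gp.kmer_k if gp.kmer_k is not None else '-'}\t"
                f"{gp.pseaac_lambda if gp.pseaac_lambda is not None else '-'}\t"
                f"{'+' if gp.physchem else '-'}\t{gp.C:g}\t{gp.t:g}\t"
                f"{r.aas_gta:.6f}\t{r.aas_virus:.6f}\t{r.was:.4f}\t{r.mcc:.4f}\n"
            )
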