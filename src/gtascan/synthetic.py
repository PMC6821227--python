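"""Seeded synthetic fixtures with the statistical structure the method assumes.

The generator emulates, at desk scale, the three structures the pipeline
relies on: (i) two sequence classes whose amino-acid compositions differ by
an alanine/glycine enrichment in the GTA-like class, mirroring the observed
compositional signature of GTA head-tail genes; (ii) genomes with planted
co-located gene clusters against a scattered background, for cluster
calling; (iii) block-structured distance matrices for weighting and outlier
filtering. Sequences are i.i.d. draws from a residue profile — sufficient
for compositional features, though k >= 2 k-mer frequencies then factor into
products of marginals, a simplification real proteins do not share.

All generators are pure functions of their parameters and the supplied
random generator/seed.
"""

from __future__ import annotations

import numpy as np

from gtascan.io import AA_ALPHABET, DistanceMatrix, SequenceRecord

_ALA_GLY = (AA_ALPHABET.index("A"), AA_ALPHABET.index("G"))


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def make_profiles(
    skew: float, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a virus residue profile and a GTA profile Ala/Gly-enriched by
    factor (1 + 2*skew) before renormalization; skew=0 gives equal profiles.
    """
    if not 0.0 <= skew <= 1.0:
        raise ValueError("skew must lie in [0, 1]")
    rng = _as_rng(rng)
    virus = rng.dirichlet(np.full(20, 5.0))
    gta = virus.copy()
    for i in _ALA_GLY:
        gta[i] *= 1.0 + 2.0 * skew
    gta /= gta.sum()
    return gta, virus


def sample_sequences(
    profile: np.ndarray,
    n: int,
    length_range: tuple[int, int] = (400, 700),
    rng: np.random.Generator | int | None = None,
    prefix: str = "seq",
) -> list[SequenceRecord]:
    """n records with i.i.d. residues from the profile, lengths uniform in range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range {length_range}")
    rng = _as_rng(rng)
    profile = np.asarray(profile, dtype=float)
    records = []
    alphabet = np.array(list(AA_ALPHABET))
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(alphabet[rng.choice(20, size=L, p=profile)])
        records.append(SequenceRecord(id=f"{prefix}{i}", sequence=seq))
    return records


def sample_training_set(
    skew: float,
    n_per_class: int = 60,
    length_range: tuple[int, int] = (400, 700),
    rng: np.random.Generator | int | None = None,
):
    """Convenience: a labelled GTA(-1)/virus(+1) set from skewed profiles."""
    from gtascan.io import make_training_set

    rng = _as_rng(rng)
    gta_profile, virus_profile = make_profiles(skew, rng)
    gta = sample_sequences(gta_profile, n_per_class, length_range, rng, prefix="gta")
    virus = sample_sequences(
        virus_profile, n_per_class, length_range, rng, prefix="vir"
    )
    return make_training_set(gta, virus)


def plant_genome(
    n_background: int,
    cluster_sizes: list[int],
    rng: np.random.Generator | int | None = None,
    eps: int = 8000,
    gene_length: int = 900,
    genome_id: str = "genome1",
    replicon_id: str = "chr1",
) -> tuple[list[SequenceRecord], list[list[str]]]:
    """Lay out background genes (gaps > eps) and planted clusters (gaps <= eps).

    Returns the loci (shuffled order) and the ground-truth member-id lists
    of the planted clusters. Sequences are placeholder poly-M of
    ``gene_length``/3 residues; only the coordinates matter downstream.
    """
    rng = _as_rng(rng)
    loci: list[SequenceRecord] = []
    truth: list[list[str]] = []
    pos = 1
    seq = "M" * max(1, gene_length // 3)

    def add(gene_id: str, start: int) -> SequenceRecord:
        rec = SequenceRecord(
            id=gene_id,
            sequence=seq,
            genome_id=genome_id,
            replicon_id=replicon_id,
            start=start,
            end=start + gene_length - 1,
            strand="+" if rng.random() < 0.5 else "-",
        )
        loci.append(rec)
        return rec

    n_slots = n_background + len(cluster_sizes)
    slot_is_cluster = [False] * n_background + [True] * len(cluster_sizes)
    rng.shuffle(slot_is_cluster)
    cluster_queue = list(cluster_sizes)
    bg_count = 0
    cl_count = 0
    for slot in range(n_slots):
        if slot_is_cluster[slot]:
            size = cluster_queue[cl_count]
            cl_count += 1
            members = []
            for j in range(size):
                rec = add(f"cl{cl_count}_g{j}", pos)
                members.append(rec.id)
                gap = int(rng.integers(0, eps + 1))  # gap <= eps keeps the chain
                pos = rec.end + 1 + gap
            truth.append(members)
        else:
            bg_count += 1
            rec = add(f"bg{bg_count}", pos)
            pos = rec.end + 1
        # spacer strictly larger than eps separates slots
        pos += eps + 1 + int(rng.integers(1, 5000))
    order = rng.permutation(len(loci))
    return [loci[i] for i in order], truth


def block_distance_matrix(
    group_sizes: list[int],
    intra: float = 0.01,
    inter: float = 1.0,
    noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
    prefix: str = "s",
) -> DistanceMatrix:
    """Symmetric matrix with within-block distance ~intra and between-block
    ~inter, plus uniform noise bounded below (inter - intra)/2 so the block
    structure stays recoverable."""
    if intra >= inter:
        raise ValueError("intra must be smaller than inter")
    if noise < 0 or noise >= (inter - intra) / 2:
        raise ValueError("noise must lie in [0, (inter - intra)/2)")
    rng = _as_rng(rng)
    n = sum(group_sizes)
    ids = [f"{prefix}{i}" for i in range(n)]
    block = np.repeat(np.arange(len(group_sizes)), group_sizes)
    base = np.where(block[:, None] == block[None, :], intra, inter).astype(float)
    if noise > 0:
        jitter = rng.uniform(-noise, noise, size=(n, n))
        jitter = (jitter + jitter.T) / 2.0
        base = np.maximum(base + jitter, 0.0)
    np.fill_diagonal(base, 0.0)
    return DistanceMatrix(ids, base)
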