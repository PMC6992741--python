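"""Energy-stratified training-set construction, permutation negatives,
P/N-ratio control, cross-validation folds and gene-list subsetting.

Training sets are drawn from an interaction table annotated with duplex
binding free energies (kcal/mol; more negative = more stable). Four modes
are supported:

``trA``
    per miRNA, the most stable pair (labelled positive) and the most
    unstable pair (labelled negative): 2 records per miRNA.
``trB``
    the two most stable vs the two most unstable pairs per miRNA:
    4 records per miRNA, with a fallback that borrows the next-ranked
    pairs of other miRNAs when a miRNA has too few candidates.
``trC``
    the extreme pair plus the two candidates nearest the per-miRNA median
    energy (ties to the more stable): 4 records per miRNA.
``trR``
    a uniform seeded random sample of the requested size.

The energy-extreme labels are a *training-label convention*, not
biological truth: the unstable half of a positive-interaction database is
labelled negative because weak duplexes are the least trustworthy
positives, and a classifier trained on the contrast learns the
energy-correlated signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from fractions import Fraction
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "InteractionRecord",
    "TrainingSet",
    "SplitPlan",
    "TRAINING_MODES",
    "rank_pairs_by_energy",
    "build_training_set",
    "generate_negatives_by_permutation",
    "enforce_pn_ratio",
    "stratified_kfold",
    "subset_by_gene_list",
]

TRAINING_MODES = ("trA", "trB", "trC", "trR")

LABELS = ("positive", "negative", "unlabelled")


@dataclass(frozen=True)
class InteractionRecord:
    mirna_id: str
    target_id: str
    label: str = "unlabelled"
    energy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def pair(self) -> tuple:
        return (self.mirna_id, self.target_id)

    def with_label(self, label: str) -> "InteractionRecord":
        return InteractionRecord(self.mirna_id, self.target_id, label, self.energy)


@dataclass
class TrainingSet:
    records: list
    mode: str
    seed: Optional[int] = None
    pn_ratio: Optional[Fraction] = None

    def __post_init__(self) -> None:
        pairs = [r.pair for r in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate pairs in training set")
        pos = {r.pair for r in self.records if r.label == "positive"}
        neg = {r.pair for r in self.records if r.label == "negative"}
        if pos & neg:
            raise ValueError("positive and negative subsets overlap")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positives(self) -> list:
        return [r for r in self.records if r.label == "positive"]

    @property
    def negatives(self) -> list:
        return [r for r in self.records if r.label == "negative"]


@dataclass
class SplitPlan:
    """k-fold assignment; ``folds[i]`` is record i's fold in 0..k-1."""

    folds: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds != fold)


def _check_unique(table: Sequence[InteractionRecord]) -> None:
    pairs = [r.pair for r in table]
    if len(set(pairs)) != len(pairs):
        raise ValueError("interaction table contains duplicate (miRNA, target) pairs")


def rank_pairs_by_energy(table: Sequence[InteractionRecord]) -> dict:
    """Per-miRNA candidate lists, most stable (lowest energy) first.

    Energy ties break by target id, lexicographically.
    """
    _check_unique(table)
    for r in table:
        if r.energy is None:
            raise ValueError(f"missing energy for pair ({r.mirna_id}, {r.target_id})")
    ranked: dict = {}
    for r in table:
        ranked.setdefault(r.mirna_id, []).append(r)
    for mirna in ranked:
        ranked[mirna].sort(key=lambda r: (r.energy, r.target_id))
    return ranked


def _mid_range(cands: Sequence[InteractionRecord], n: int) -> list:
    """The n candidates with energy nearest the per-miRNA median; ties to
    the more stable (lower-energy) candidate."""
    median = float(np.median([r.energy for r in cands]))
    order = sorted(cands, key=lambda r: (abs(r.energy - median), r.energy, r.target_id))
    return order[:n]


def build_training_set(
    table: Sequence[InteractionRecord],
    mode: str,
    seed: Optional[int] = None,
    size: Optional[int] = None,
) -> TrainingSet:
    """Build one of the four training sets from an energy-annotated table.

    For M miRNAs, trA holds 2M records and trB/trC 4M. When a miRNA has
    fewer candidates than its quota, the unfilled slots are taken from the
    next-ranked unused pairs of the other miRNAs (most stable remaining for
    positive slots, most unstable remaining for negative slots), so totals
    stay fixed. trR draws ``size`` records uniformly (default 4M) and keeps
    the table's labels (unlabelled if absent).
    """
    if mode not in TRAINING_MODES:
        raise ValueError(f"mode must be one of {TRAINING_MODES}, got {mode!r}")
    if not table:
        raise ValueError("empty interaction table")

    if mode == "trR":
        if seed is None:
            raise ValueError("trR requires a seed")
        n_mirnas = len({r.mirna_id for r in table})
        size = 4 * n_mirnas if size is None else size
        if size > len(table):
            raise ValueError(f"requested trR size {size} exceeds table size {len(table)}")
        rng = np.random.default_rng(seed)
        order = sorted(table, key=lambda r: r.pair)
        idx = rng.choice(len(order), size=size, replace=False)
        return TrainingSet([order[i] for i in sorted(idx)], mode="trR", seed=seed)

    ranked = rank_pairs_by_energy(table)
    per_side = 1 if mode == "trA" else 2

    pos: list = []
    neg: list = []
    used: set = set()
    pos_deficit = neg_deficit = 0
    for mirna in sorted(ranked):
        cands = ranked[mirna]
        if mode == "trC":
            # one extreme pair + the two mid-range candidates
            want_pos = [cands[0]]
            want_neg = [cands[-1]] if len(cands) > 1 else []
            pool = [r for r in cands if r.pair not in {w.pair for w in want_pos + want_neg}]
            mids = _mid_range(pool, 2) if pool else []
            # the more stable mid-range pick is labelled positive
            mids.sort(key=lambda r: (r.energy, r.target_id))
            if mids:
                want_pos.append(mids[0])
            if len(mids) > 1:
                want_neg.append(mids[1])
        else:
            stable = cands[:per_side]
            unstable = [c for c in reversed(cands) if c.pair not in {s.pair for s in stable}]
            want_pos = stable
            want_neg = unstable[:per_side]
        pos_deficit += per_side - len(want_pos)
        neg_deficit += per_side - len(want_neg)
        pos.extend(want_pos)
        neg.extend(want_neg)
        used.update(r.pair for r in want_pos + want_neg)

    if pos_deficit or neg_deficit:
        # borrow next-ranked pairs of other miRNAs, keeping totals fixed
        leftovers = sorted(
            (r for m in ranked for r in ranked[m] if r.pair not in used),
            key=lambda r: (r.energy, r.target_id),
        )
        if pos_deficit + neg_deficit > len(leftovers):
            raise ValueError("not enough candidate pairs to fill the training set")
        for _ in range(pos_deficit):
            r = leftovers.pop(0)  # most stable remaining
            pos.append(r)
            used.add(r.pair)
        for _ in range(neg_deficit):
            r = leftovers.pop()  # most unstable remaining
            neg.append(r)
            used.add(r.pair)

    records = [r.with_label("positive") for r in pos] + [
        r.with_label("negative") for r in neg
    ]
    return TrainingSet(records, mode=mode, seed=seed, pn_ratio=Fraction(1, 1))


def generate_negatives_by_permutation(
    positives: Iterable[tuple],
    gene_universe: Iterable[str],
    seed: int,
    n: int,
) -> list:
    """Draw n non-positive (miRNA, gene) pairs uniformly, without replacement.

    Mock negatives by re-pairing: the candidate space is the Cartesian
    product of the positives' miRNAs with the gene universe, minus the
    known positives.
    """
    positives = set(positives)
    mirnas = sorted({m for m, _ in positives})
    universe = sorted(set(gene_universe))
    total = len(mirnas) * len(universe) - len(
        {p for p in positives if p[1] in set(universe)}
    )
    if n > total:
        raise ValueError(
            f"cannot draw {n} negatives: only {total} non-positive combinations exist"
        )
    rng = np.random.default_rng(seed)
    space = len(mirnas) * len(universe)
    if space <= 2_000_000:
        candidates = [
            (m, g) for m in mirnas for g in universe if (m, g) not in positives
        ]
        idx = rng.choice(len(candidates), size=n, replace=False)
        return [candidates[i] for i in sorted(idx)]
    # large space: rejection sampling without replacement
    chosen: set = set()
    out: list = []
    while len(out) < n:
        i = int(rng.integers(space))
        pair = (mirnas[i // len(universe)], universe[i % len(universe)])
        if pair in positives or pair in chosen:
            continue
        chosen.add(pair)
        out.append(pair)
    return out


def enforce_pn_ratio(
    pos: Sequence,
    neg: Sequence,
    ratio: Union[Fraction, float, tuple],
    seed: int,
) -> tuple:
    """Subsample (without replacement) to an exact positive:negative ratio.

    ``ratio`` is positives per negative: 1 means 1:1, ``Fraction(1, 2)`` or
    ``(1, 2)`` means 1:2. Takes the largest subsets achieving the exact
    ratio; the larger side is down-sampled with the given seed.
    """
    if isinstance(ratio, tuple):
        ratio = Fraction(*ratio)
    ratio = Fraction(ratio).limit_denominator(10**6)
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    a, b = ratio.numerator, ratio.denominator
    k = min(len(pos) // a, len(neg) // b)
    if k == 0:
        raise ValueError(
            f"ratio {a}:{b} unattainable with {len(pos)} positives and {len(neg)} negatives"
        )
    rng = np.random.default_rng(seed)

    def sample(items: Sequence, m: int) -> list:
        if m == len(items):
            return list(items)
        idx = rng.choice(len(items), size=m, replace=False)
        return [items[i] for i in sorted(idx)]

    return sample(pos, k * a), sample(neg, k * b)


def stratified_kfold(labels: Sequence, k: int, seed: int) -> SplitPlan:
    """Seeded stratified k-fold plan; per-fold class counts within 1 of balance."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class size {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(labels), 1)), labels)):
        folds[test_idx] = fold
    return SplitPlan(folds=folds, k=k)


def subset_by_gene_list(
    records: Sequence[InteractionRecord], gene_ids: Iterable[str]
) -> list:
    """Records whose target is in the gene list; input order preserved.

    Used to evaluate performance on functionally annotated (e.g. GO-term)
    gene subsets.
    """
    wanted = set(gene_ids)
    return [r for r in records if r.target_id in wanted]
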