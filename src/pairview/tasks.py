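"""Task-level prediction APIs, data splits, unit conversion and metrics.

Covers synergy classification (with the three-drug extension), xenograft
BestResponse / temporal regression, DDI negative sampling, the five split
protocols with their leakage constraints, FPKM->TPM conversion and the
evaluation metrics used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm

from .data import ExpressionMatrix, TripletRecord
from .model import DrugCombinationModel

DECISION_THRESHOLD = 0.5  # p >= 0.5 maps to the positive class


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_synergy(model: DrugCombinationModel, triplet: TripletRecord,
                    average_orders: bool = False) -> tuple[float, int]:
    """Aggregated synergy probability and the binary call at threshold 0.5
    (the boundary p == 0.5 maps to the positive class).

    With `average_orders`, the prediction is the mean over both drug orders
    (the model input is otherwise ordered, anchor first).
    """
    p = float(model.predict([triplet])[0])
    if average_orders:
        swapped = TripletRecord(triplet.drug_b, triplet.drug_a,
                                triplet.context_id, triplet.label,
                                triplet.time_days)
        p = 0.5 * (p + float(model.predict([swapped])[0]))
    return p, int(p >= DECISION_THRESHOLD)


def predict_three_drug(model: DrugCombinationModel, drug_a: str, drug_b: str,
                       drug_c: str, context_id: str) -> float:
    """Three-drug synergy: the mean of the three pairwise predictions.

    Each pair is presented in canonical (lexicographic) order so the result
    is invariant to the listing order of the three drugs.
    """
    ids = [drug_a, drug_b, drug_c]
    if len(set(ids)) != 3:
        raise ValueError("three-drug prediction requires three distinct drugs")
    pairs = [tuple(sorted(p)) for p in
             [(drug_a, drug_b), (drug_a, drug_c), (drug_b, drug_c)]]
    triplets = [TripletRecord(a, b, context_id, 0.0) for a, b in sorted(pairs)]
    return float(np.mean(model.predict(triplets)))


# ---------------------------------------------------------------------------
# xenograft
# ---------------------------------------------------------------------------

@dataclass
class XenograftTrajectory:
    """Relative tumor-volume changes over days for one (model, drug pair)."""

    model_id: str
    drug_a: str
    drug_b: str
    points: list[tuple[int, float]]  # (day, delta_vol)

    def __post_init__(self):
        days = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("time points must be strictly increasing")
        for t, dv in self.points:
            if t == 0 and dv != 0.0:
                raise ValueError("delta volume at day 0 must be 0")


def best_response(trajectory: XenograftTrajectory, min_day: int = 10) -> float:
    """Minimum relative volume change over all time points at or after day 10."""
    late = [dv for t, dv in trajectory.points if t >= min_day]
    if not late:
        raise ValueError(
            f"trajectory {trajectory.model_id}: no time point at or after day {min_day}")
    return min(late)


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM: each entry is divided by its column sum and scaled
    by 1e6, so every context column sums to one million.  Idempotent on
    already-TPM-normalized input."""
    values = matrix.values
    colsums = values.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"all-zero expression column(s): {list(zero.index)}")
    return ExpressionMatrix(values / colsums * 1e6, "TPM")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

SPLIT_MODES = ("vanilla", "by_combination", "by_cell_line",
               "ddi_one_new_drug", "ddi_two_new_drugs")


@dataclass
class SplitSpec:
    mode: str = "vanilla"
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in SPLIT_MODES:
            raise ValueError(f"unknown split mode {self.mode!r}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class Splits:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        all_idx = np.concatenate([self.train, self.valid, self.test])
        if len(set(all_idx.tolist())) != len(all_idx):
            raise ValueError("split index sets overlap")


def _cut(items: list, fractions, rng: np.random.Generator):
    perm = rng.permutation(len(items))
    n = len(items)
    n_train = int(round(fractions[0] * n))
    n_valid = int(round(fractions[1] * n))
    tr = [items[i] for i in perm[:n_train]]
    va = [items[i] for i in perm[n_train:n_train + n_valid]]
    te = [items[i] for i in perm[n_train + n_valid:]]
    return tr, va, te


def make_splits(triplets: list[TripletRecord], spec: SplitSpec) -> Splits:
    """Seeded train/valid/test partition under the chosen leakage constraint.

    vanilla: random over triplets.  by_combination: unordered drug pairs are
    split, so no test pair occurs in train.  by_cell_line: contexts are split.
    ddi_one_new_drug / ddi_two_new_drugs: a drug subset is held out; test
    pairs contain exactly one / exactly two held-out drugs and train pairs
    contain none (remaining triplets fall to validation).
    """
    if not triplets:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(spec.seed)
    n = len(triplets)
    if spec.mode == "vanilla":
        tr, va, te = _cut(list(range(n)), spec.fractions, rng)
        return Splits(np.array(sorted(tr)), np.array(sorted(va)), np.array(sorted(te)))

    if spec.mode in ("by_combination", "by_cell_line"):
        if spec.mode == "by_combination":
            keyfn = lambda t: t.pair_key()
        else:
            keyfn = lambda t: t.context_id
        keys = sorted({keyfn(t) for t in triplets})
        if len(keys) < 3:
            raise ValueError(f"too few groups ({len(keys)}) for mode {spec.mode}")
        tr_k, va_k, te_k = (set(s) for s in _cut(keys, spec.fractions, rng))
        groups = {"train": [], "valid": [], "test": []}
        for i, t in enumerate(triplets):
            k = keyfn(t)
            groups["train" if k in tr_k else "valid" if k in va_k else "test"].append(i)
        if not groups["train"] or not groups["test"]:
            raise ValueError("dataset too small for the requested split")
        return Splits(*(np.array(groups[s]) for s in ("train", "valid", "test")))

    # DDI new-drug modes: hold out enough drugs that the expected test
    # fraction matches the requested one (test pairs have exactly one / two
    # held-out drugs, so the pair-level fraction is 2h(1-h) / h^2 for a
    # held-out drug fraction h)
    drugs = sorted({t.drug_a for t in triplets} | {t.drug_b for t in triplets})
    f_test = spec.fractions[2]
    if spec.mode == "ddi_two_new_drugs":
        h = np.sqrt(f_test)
    else:
        h = (1.0 - np.sqrt(max(0.0, 1.0 - 2.0 * f_test))) / 2.0
    n_new = max(1, int(round(h * len(drugs))))
    if n_new >= len(drugs):
        raise ValueError("dataset too small to hold out new drugs")
    new = set(np.array(drugs)[rng.permutation(len(drugs))[:n_new]].tolist())
    want = 1 if spec.mode == "ddi_one_new_drug" else 2
    test_idx, pool, leftover = [], [], []
    for i, t in enumerate(triplets):
        k = int(t.drug_a in new) + int(t.drug_b in new)
        if k == want:
            test_idx.append(i)
        elif k == 0:
            pool.append(i)
        else:
            leftover.append(i)
    f_tr, f_va = spec.fractions[0], spec.fractions[1]
    tr, va, rest = _cut(pool, (f_tr / (f_tr + f_va), f_va / (f_tr + f_va), 0.0), rng)
    va = sorted(va + rest + leftover)
    if not tr or not test_idx:
        raise ValueError("dataset too small for the requested new-drug split")
    return Splits(np.array(sorted(tr)), np.array(va), np.array(sorted(test_idx)))


def check_split_constraint(triplets: list[TripletRecord], splits: Splits,
                           mode: str) -> bool:
    """Exhaustive membership scan verifying the leakage constraint."""
    train = [triplets[i] for i in splits.train]
    test = [triplets[i] for i in splits.test]
    if mode == "by_combination":
        seen = {t.pair_key() for t in train}
        return all(t.pair_key() not in seen for t in test)
    if mode == "by_cell_line":
        seen = {t.context_id for t in train}
        return all(t.context_id not in seen for t in test)
    if mode in ("ddi_one_new_drug", "ddi_two_new_drugs"):
        seen = {t.drug_a for t in train} | {t.drug_b for t in train}
        want = 1 if mode == "ddi_one_new_drug" else 2
        return all(int(t.drug_a not in seen) + int(t.drug_b not in seen) == want
                   for t in test)
    return True  # vanilla has no constraint beyond partitioning


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def classification_metrics(labels, scores,
                           threshold: float = DECISION_THRESHOLD) -> dict:
    """BACC, AUPRC (step-interpolated), F1 and Cohen's kappa at threshold 0.5."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("threshold metrics need both classes present")
    calls = (scores >= threshold).astype(int)
    return {
        "bacc": float(skm.balanced_accuracy_score(labels, calls)),
        "auprc": float(skm.average_precision_score(labels, scores)),
        "f1": float(skm.f1_score(labels, calls, zero_division=0)),
        "kappa": float(skm.cohen_kappa_score(labels, calls)),
    }


def regression_metrics(labels, predictions) -> dict:
    """Spearman and Pearson correlations (average ranks on ties)."""
    labels = np.asarray(labels, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    return {
        "spearman": float(sps.spearmanr(labels, predictions).statistic),
        "pearson": float(sps.pearsonr(labels, predictions).statistic),
    }


# ---------------------------------------------------------------------------
# DDI negative sampling
# ---------------------------------------------------------------------------

def negative_sample_ddi(positives, drugs, types, rng: np.random.Generator,
                        n: Optional[int] = None,
                        preserve_type_marginal: bool = False) -> list[tuple]:
    """Uniform negatives over (unordered drug pair, type) triples absent from
    the positive set; matched in count to the positives, without duplicates.

    With `preserve_type_marginal`, each negative reuses a positive's type so
    the per-type counts match the positive distribution.
    """
    drugs = sorted(drugs)
    types = sorted(types)
    pos = {(*sorted((a, b)), t) for a, b, t in positives}
    n = len(pos) if n is None else n
    n_pairs = len(drugs) * (len(drugs) - 1) // 2
    if n > n_pairs * len(types) - len(pos):
        raise ValueError("negative space exhausted")
    pos_types = sorted(t for *_, t in pos)
    out: set[tuple] = set()
    while len(out) < n:
        a, b = rng.choice(len(drugs), size=2, replace=False)
        a, b = sorted((drugs[a], drugs[b]))
        if preserve_type_marginal:
            t = pos_types[int(rng.integers(len(pos_types)))]
        else:
            t = types[int(rng.integers(len(types)))]
        cand = (a, b, t)
        if cand not in pos and cand not in out:
            out.add(cand)
    return sorted(out)


def view_inventory(model: DrugCombinationModel,
                   triplets: list[TripletRecord]) -> pd.DataFrame:
    """Per-triplet audit of available modality-pair views."""
    from .views import enumerate_views

    rows = []
    for i, t in enumerate(triplets):
        keys = enumerate_views(model.availability(t.drug_a),
                               model.availability(t.drug_b))
        rows.append({
            "triplet_id": i, "drug_a": t.drug_a, "drug_b": t.drug_b,
            "context_id": t.context_id, "n_views": len(keys),
            "keys": ";".join(f"{a.value}|{b.value}" for a, b in keys),
        })
    return pd.DataFrame(rows)
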