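"""Downstream interpretation: novel-triplet enumeration, SDL-filtered
drug-sensitive pathway mining, patient pathway-activation labels, and the
Fisher's-exact drug-class interaction network.

SDL (synthetic dosage lethality) pairs are directed (overactive gene,
essential gene): over-activity of the first makes the second essential, so a
drug inhibiting the second is selectively lethal where the first is high.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger("pairview")


# ---------------------------------------------------------------------------
# candidate triplets
# ---------------------------------------------------------------------------

def enumerate_candidate_triplets(drugs, contexts, observed):
    """All unobserved drug-pair/context triplets.

    The ordered candidate space has |drugs|·(|drugs|-1)·|contexts| triplets
    (anchor/library order distinguished).  A triplet is novel iff neither
    order appears in `observed`; the novel set is deduplicated to canonical
    (lexicographic) pair order.  Returns (ordered_count, novel_triplets).
    """
    drugs = sorted(set(drugs))
    contexts = sorted(set(contexts))
    if not drugs or not contexts:
        raise ValueError("drug and context lists must be nonempty")
    drugset = set(drugs)
    obs = set()
    for a, b, c in observed:
        if a not in drugset or b not in drugset:
            raise ValueError(f"observed triplet references unknown drug: {(a, b)}")
        obs.add((a, b, c))
    ordered_count = len(drugs) * (len(drugs) - 1) * len(contexts)
    novel = []
    for a, b in itertools.combinations(drugs, 2):  # a < b: canonical order
        for c in contexts:
            if (a, b, c) not in obs and (b, a, c) not in obs:
                novel.append((a, b, c))
    return ordered_count, novel


# ---------------------------------------------------------------------------
# gene pairs and the SDL filter
# ---------------------------------------------------------------------------

@dataclass
class GenePairSet:
    """(overactive gene, essential gene) pairs with supporting-triplet counts."""

    support: dict[tuple[str, str], int] = field(default_factory=dict)
    skipped: int = 0

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.support)


def build_gene_pairs(predicted, threshold: float, drug_targets: dict,
                     overexpressed: dict) -> GenePairSet:
    """Gene pairs from confidently predicted novel triplets.

    For every triplet (a, b, context) with prediction >= `threshold`, pair
    each over-expressed gene of the context (overactive role) with each
    target gene of the drug combination (essential role), excluding pairs
    where the two genes coincide.  Triplets lacking targets or over-expressed
    genes contribute nothing and are counted in `skipped`.
    """
    out = GenePairSet()
    for (a, b, c), prob in predicted:
        if not (0.0 < prob < 1.0):
            raise ValueError(f"prediction {prob} outside (0, 1)")
        if prob < threshold:
            continue
        targets = set(drug_targets.get(a, ())) | set(drug_targets.get(b, ()))
        over = set(overexpressed.get(c, ()))
        if not targets or not over:
            out.skipped += 1
            continue
        for g_over in over:
            for g_ess in targets:
                if g_over == g_ess:
                    continue
                key = (g_over, g_ess)
                out.support[key] = out.support.get(key, 0) + 1
    if out.skipped:
        logger.info("%d triplet(s) lacked targets or over-expressed genes", out.skipped)
    return out


@dataclass
class PathwayResult:
    """SDL-surviving gene pairs (overactive, essential) with support counts."""

    pairs: set[tuple[str, str]]
    support: dict[tuple[str, str], int]

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}


def filter_sdl(gene_pairs: GenePairSet, sdl_pairs: set) -> PathwayResult:
    """Keep only gene pairs present in the SDL network (orientation:
    overactive = over-expressed context gene, essential = drug target)."""
    kept = gene_pairs.pairs & set(sdl_pairs)
    return PathwayResult(kept, {p: gene_pairs.support[p] for p in kept})


# ---------------------------------------------------------------------------
# patient stratification
# ---------------------------------------------------------------------------

def patient_pathway_label(expression, mutations, pathway: PathwayResult,
                          cohort) -> bool:
    """Pathway-activation label for one patient.

    A gene is highly expressed iff its value strictly exceeds the cohort's
    70th percentile, and inhibited iff it is mutated or strictly below the
    30th percentile (lower than 70% of patients).  The pathway is activated
    iff at least one (overactive, essential) pair has the overactive gene
    highly expressed and the essential gene inhibited.  Pairs with genes
    absent from the cohort matrix are skipped.
    """
    mutations = set(mutations)
    cohort_genes = set(map(str, cohort.index))

    def high(g):
        return float(expression[g]) > float(np.percentile(cohort.loc[g].values, 70))

    def inhibited(g):
        if g in mutations:
            return True
        return float(expression[g]) < float(np.percentile(cohort.loc[g].values, 30))

    for g_over, g_ess in sorted(pathway.pairs):
        if g_over not in cohort_genes or g_ess not in cohort_genes:
            logger.info("pair (%s, %s) skipped: gene absent from cohort", g_over, g_ess)
            continue
        if g_over not in expression or g_ess not in expression:
            continue
        if high(g_over) and inhibited(g_ess):
            return True
    return False


# ---------------------------------------------------------------------------
# Fisher's exact test and the DDI class network
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")


def fishers_exact(table: ContingencyTable2x2, sided: str = "greater") -> float:
    """Exact hypergeometric p-value for a 2x2 table.

    One-sided "greater" tests enrichment of the (a) cell; "two-sided" uses the
    point-probability rule (sum of all tables no more probable than the
    observed one).  Degenerate margins give p = 1 with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        logger.warning("degenerate contingency margins; p = 1")
        return 1.0
    rv = hypergeom(n, row1, col1)
    if sided == "greater":
        return float(rv.sf(a - 1))
    if sided == "two-sided":
        lo, hi = max(0, row1 + col1 - n), min(row1, col1)
        support = np.arange(lo, hi + 1)
        pmf = rv.pmf(support)
        return float(pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum())
    raise ValueError(f"unknown sidedness {sided!r}")


def ddi_class_network(predictions, drug_classes: dict, top_types: int = 50,
                      prob_threshold: float = 0.9, per_drug_cap: int = 100,
                      alpha: float = 0.05, sided: str = "greater"):
    """Drug-class interaction network from high-confidence DDI predictions.

    Restrict to the `top_types` most frequent interaction types, drop
    predictions below `prob_threshold`, keep each drug's `per_drug_cap` most
    confident interactions (an interaction survives if it makes the cap for
    at least one of its two drugs), then test each (class pair, type) cell
    with Fisher's exact test against the surviving background and keep edges
    with p < alpha.

    `predictions` is an iterable of (drug_a, drug_b, type_id, probability);
    `drug_classes` maps a drug to one or more ontology classes (a drug in
    several classes counts in each class pair).  Returns a sorted list of
    (class_a, class_b, type_id, p_value).
    """
    predictions = list(predictions)
    freq = Counter(t for *_, t, _ in [(a, b, t, p) for a, b, t, p in predictions])
    kept_types = {t for t, _ in sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
                  [:top_types]}
    conf = [(a, b, t, p) for a, b, t, p in predictions
            if t in kept_types and p >= prob_threshold]
    # per-drug confidence cap
    by_drug: dict[str, list] = {}
    for rec in conf:
        a, b, t, p = rec
        by_drug.setdefault(a, []).append(rec)
        by_drug.setdefault(b, []).append(rec)
    allowed = set()
    for recs in by_drug.values():
        recs = sorted(recs, key=lambda r: (-r[3], r[0], r[1], r[2]))
        allowed.update(id(r) for r in recs[:per_drug_cap])
    surviving = [r for r in conf if id(r) in allowed]
    if not surviving:
        logger.warning("no interaction survives filtering; empty network")
        return []

    occ = Counter()
    type_tot = Counter()
    pair_tot = Counter()
    total = 0
    for a, b, t, _ in surviving:
        cls_pairs = {tuple(sorted((ca, cb)))
                     for ca in drug_classes.get(a, ())
                     for cb in drug_classes.get(b, ())}
        for cp in cls_pairs:
            occ[(cp, t)] += 1
            pair_tot[cp] += 1
            type_tot[t] += 1
            total += 1

    edges = []
    for (cp, t), a_cnt in sorted(occ.items()):
        tab = ContingencyTable2x2(
            a=a_cnt, b=pair_tot[cp] - a_cnt,
            c=type_tot[t] - a_cnt,
            d=total - pair_tot[cp] - type_tot[t] + a_cnt)
        p = fishers_exact(tab, sided=sided)
        if p < alpha:
            edges.append((cp[0], cp[1], t, p))
    return sorted(edges)
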