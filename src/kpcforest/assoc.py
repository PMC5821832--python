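"""Market basket analysis: discretization, Apriori mining, rule filtering,
network export.

Continuous variables become transaction items by a median split
("<name>=high" / "<name>=low"); frequent itemsets are mined level-wise with
the downward-closure prune and turned into association rules filtered on
support, confidence and lift (defaults 0.0625 / 0.25 / 1.2).  Rule networks
are exported as SIF and GraphML for Cytoscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 0.0625
DEFAULT_MIN_CONFIDENCE = 0.25
DEFAULT_MIN_LIFT = 1.2
DEFAULT_MAX_LEN = 3


class AssocError(ValueError):
    pass


@dataclass
class TransactionSet:
    """Per-sample sets of item labels."""

    transactions: list[frozenset[str]]
    sample_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.transactions = [frozenset(t) for t in self.transactions]

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for t in self.transactions:
            out |= t
        return out

    def __len__(self) -> int:
        return len(self.transactions)

    def write_baskets(self, path) -> None:
        """One line per sample: tab-separated sorted items (basket format)."""
        with open(path, "w") as fh:
            for i, t in enumerate(self.transactions):
                sid = self.sample_ids[i] if self.sample_ids else f"s{i}"
                fh.write(sid + "\t" + "\t".join(sorted(t)) + "\n")

    @classmethod
    def read_baskets(cls, path) -> "TransactionSet":
        sample_ids, transactions = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                sample_ids.append(parts[0])
                transactions.append(frozenset(p for p in parts[1:] if p))
        return cls(transactions, sample_ids)


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise AssocError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise AssocError("antecedent and consequent must be disjoint")


@dataclass
class RuleSet:
    rules: list[AssociationRule]

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "antecedent": ",".join(sorted(r.antecedent)),
                "consequent": ",".join(sorted(r.consequent)),
                "support": r.support,
                "confidence": r.confidence,
                "lift": r.lift,
            }
            for r in self.rules
        ]
        df = pd.DataFrame(
            rows, columns=["antecedent", "consequent", "support", "confidence", "lift"]
        )
        return df.sort_values(
            ["lift", "support", "antecedent", "consequent"],
            ascending=[False, False, True, True],
        ).reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RuleSet":
        rules = [
            AssociationRule(
                frozenset(str(r.antecedent).split(",")),
                frozenset(str(r.consequent).split(",")),
                float(r.support),
                float(r.confidence),
                float(r.lift),
            )
            for r in df.itertuples()
        ]
        return cls(rules)


def discretize(
    matrix: FeatureMatrix,
    scheme: str = "median",
    n_bins: int = 3,
) -> TransactionSet:
    """Turn a numeric table into transactions.

    ``median`` (default): values strictly above the column median emit
    "<name>=high", strictly below emit "<name>=low", values at the median emit
    nothing.  ``quantile``: ``n_bins`` equal-frequency bins emitting
    "<name>=q<i>" (samples at internal bin edges go to the lower bin).
    Constant variables emit no items.
    """
    if matrix.n_samples < 1:
        raise AssocError("need at least one sample")
    items: list[set[str]] = [set() for _ in range(matrix.n_samples)]
    for j, name in enumerate(matrix.variable_names):
        col = matrix.values[:, j]
        if np.all(col == col[0]):
            logger.info("discretize: variable %r is constant; no items emitted", name)
            continue
        if scheme == "median":
            med = np.median(col)
            for i, v in enumerate(col):
                if v > med:
                    items[i].add(f"{name}=high")
                elif v < med:
                    items[i].add(f"{name}=low")
        elif scheme == "quantile":
            edges = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
            bins = np.searchsorted(edges, col, side="left")
            for i, b in enumerate(bins):
                items[i].add(f"{name}=q{b + 1}")
        else:
            raise AssocError(f"unknown discretization scheme {scheme!r}")
    return TransactionSet(
        [frozenset(s) for s in items], sample_ids=list(matrix.sample_ids)
    )


def _item_matrix(transactions: TransactionSet):
    items = sorted(transactions.universe)
    index = {it: i for i, it in enumerate(items)}
    B = np.zeros((len(items), len(transactions)), dtype=bool)
    for s, t in enumerate(transactions.transactions):
        for it in t:
            B[index[it], s] = True
    return items, B


def apriori(
    transactions: TransactionSet,
    min_support: float = DEFAULT_MIN_SUPPORT,
    max_len: int = DEFAULT_MAX_LEN,
) -> dict[frozenset[str], float]:
    """All itemsets of size <= ``max_len`` with support >= ``min_support``.

    Level-wise candidate generation with the downward-closure prune; supports
    are exact transaction counts over n.
    """
    if not 0 < min_support <= 1:
        raise AssocError("min_support must be in (0, 1]")
    if len(transactions) == 0:
        raise AssocError("empty transaction set")
    n = len(transactions)
    items, B = _item_matrix(transactions)
    supports: dict[frozenset[str], float] = {}
    cover = {}  # itemset -> boolean presence vector over transactions
    current: list[tuple[str, ...]] = []
    for i, it in enumerate(items):
        s = B[i].sum() / n
        if s >= min_support:
            supports[frozenset([it])] = s
            cover[(it,)] = B[i]
            current.append((it,))
    k = 1
    while current and k < max_len:
        current.sort()
        nxt: list[tuple[str, ...]] = []
        frequent_prev = set(current)
        for a_idx in range(len(current)):
            a = current[a_idx]
            for b_idx in range(a_idx + 1, len(current)):
                b = current[b_idx]
                if a[:-1] != b[:-1]:
                    break  # sorted prefixes diverge: no further joins for a
                cand = a + (b[-1],)
                # downward closure: every k-subset must be frequent
                if any(
                    tuple(sub) not in frequent_prev
                    for sub in combinations(cand, k)
                ):
                    continue
                vec = cover[a] & cover[(b[-1],)]
                s = vec.sum() / n
                if s >= min_support:
                    supports[frozenset(cand)] = s
                    cover[cand] = vec
                    nxt.append(cand)
        current = nxt
        k += 1
    return supports


def generate_rules(
    itemsets: dict[frozenset[str], float],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    min_lift: float = DEFAULT_MIN_LIFT,
) -> RuleSet:
    """All antecedent -> consequent partitions of the frequent itemsets that
    meet the confidence and lift thresholds.

    support(rule) = support(antecedent u consequent); confidence =
    support(rule)/support(antecedent); lift = confidence/support(consequent).
    """
    rules: list[AssociationRule] = []
    for itemset, supp in itemsets.items():
        if len(itemset) < 2:
            continue
        members = sorted(itemset)
        for r in range(1, len(members)):
            for ante in combinations(members, r):
                A = frozenset(ante)
                C = itemset - A
                if A not in itemsets or C not in itemsets:
                    continue  # cannot happen for downward-closed input
                confidence = supp / itemsets[A]
                lift = confidence / itemsets[C]
                if confidence >= min_confidence and lift >= min_lift:
                    rules.append(AssociationRule(A, C, supp, confidence, lift))
    return RuleSet(rules)


def mine_rules(
    transactions: TransactionSet,
    min_support: float = DEFAULT_MIN_SUPPORT,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    min_lift: float = DEFAULT_MIN_LIFT,
    max_len: int = DEFAULT_MAX_LEN,
) -> RuleSet:
    """Convenience: apriori followed by rule generation."""
    return generate_rules(
        apriori(transactions, min_support, max_len), min_confidence, min_lift
    )


def rules_graph(rules: RuleSet) -> nx.DiGraph:
    """Item-level directed graph: one edge per antecedent-item/consequent-item
    pair, attributed with the best (highest-lift) rule connecting them."""
    G = nx.DiGraph()
    for rule in rules:
        for a in sorted(rule.antecedent):
            for c in sorted(rule.consequent):
                if G.has_edge(a, c) and G[a][c]["lift"] >= rule.lift:
                    continue
                G.add_edge(
                    a,
                    c,
                    support=rule.support,
                    confidence=rule.confidence,
                    lift=rule.lift,
                )
    return G


def export_network(rules: RuleSet, basepath) -> tuple[Path, Path]:
    """Write the rule network as SIF and GraphML next to ``basepath``.

    Returns the two paths written.  Both formats load in Cytoscape; edge
    attributes (support, confidence, lift) travel in the GraphML file.
    """
    if len(rules) == 0:
        raise AssocError("cannot export an empty rule set")
    base = Path(basepath)
    sif_path = base.with_suffix(".sif")
    graphml_path = base.with_suffix(".graphml")
    G = rules_graph(rules)
    try:
        with open(sif_path, "w") as fh:
            for a, c in sorted(G.edges()):
                fh.write(f"{a}\tassoc\t{c}\n")
        nx.write_graphml(G, graphml_path)
    except OSError as exc:
        raise AssocError(f"failed writing network files at {base}: {exc}") from exc
    return sif_path, graphml_path
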