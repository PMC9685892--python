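"""Apriori search for diagnosis combinations predicting in-hospital death.

Rules have the form X => death, where X is a combination of one to four
prefix-named diagnosis indicators. The search is the classical levelwise
Apriori: an itemset can only reach the support floor if every subset
does (anti-monotonicity), so candidates of size k are joined from
frequent sets of size k-1 and pruned before counting. Counting uses
packed patient bitsets: each item's carrier vector is packed to bytes
once, candidate counts are popcounts of intersected parents.

Metrics per rule (N patients, D deaths, antecedent carried by n_x of
whom n_xy died):

* coverage      = n_x / N            (left-hand support as a proportion)
* confidence    = n_xy / n_x         (mortality among carriers)
* lift_outcome  = confidence / (D/N)
* lift_cooccurrence = n_x / (N * prod_j prevalence_j)

Two lift variants are kept deliberately: the classical market-basket
definition of lift compares the antecedent's observed co-occurrence to
independence (``lift_cooccurrence``), while mortality-rule reports in
this domain print confidence over baseline mortality
(``lift_outcome``). Both are computed; reports label them explicitly.

The support floor is an absolute carrier count on the antecedent alone
(default 25 subjects), outcome-agnostic. No minimum-confidence cutoff is
applied anywhere: ranking, not thresholding, orders the output.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .code_mapping import IndicatorMatrix

logger = logging.getLogger("ihtminer")

_BRUTE_FORCE_MAX_ITEMS = 16


class MiningError(ValueError):
    """Raised for invalid mining configurations or inputs."""


@dataclass(frozen=True)
class MiningConfig:
    """Search constraints: support floor in subjects and antecedent order."""

    min_antecedent_count: int = 25
    max_order: int = 4
    lift_mode: str = "both"

    def __post_init__(self) -> None:
        if self.min_antecedent_count < 1:
            raise MiningError("min_antecedent_count must be >= 1")
        if self.max_order < 1:
            raise MiningError("max_order must be >= 1")
        if self.lift_mode not in ("outcome", "cooccurrence", "both"):
            raise MiningError("lift_mode must be outcome, cooccurrence or both")


@dataclass(frozen=True)
class ItemSet:
    """A sorted antecedent with its carrier count."""

    items: tuple[str, ...]
    count: int

    def __post_init__(self) -> None:
        if tuple(sorted(self.items)) != self.items:
            raise MiningError("items must be sorted")
        if len(set(self.items)) != len(self.items):
            raise MiningError("items must be unique")
        if self.count < 0:
            raise MiningError("count must be >= 0")

    @property
    def order(self) -> int:
        return len(self.items)


@dataclass
class Rule:
    """One antecedent => death rule with its exact-count metrics."""

    antecedent: tuple[str, ...]
    n_antecedent: int
    n_both: int
    coverage: float
    confidence: float
    lift_outcome: float | None
    lift_cooccurrence: float | None
    improvement: float | None = None
    binding_subrule: tuple[str, ...] | None = None

    @property
    def order(self) -> int:
        return len(self.antecedent)

    def to_dict(self) -> dict:
        return {
            "antecedent": list(self.antecedent),
            "n_antecedent": self.n_antecedent,
            "n_both": self.n_both,
            "coverage": self.coverage,
            "confidence": self.confidence,
            "lift_outcome": self.lift_outcome,
            "lift_cooccurrence": self.lift_cooccurrence,
            "improvement": self.improvement,
            "binding_subrule": list(self.binding_subrule)
            if self.binding_subrule is not None
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        return cls(
            antecedent=tuple(d["antecedent"]),
            n_antecedent=d["n_antecedent"],
            n_both=d["n_both"],
            coverage=d["coverage"],
            confidence=d["confidence"],
            lift_outcome=d.get("lift_outcome"),
            lift_cooccurrence=d.get("lift_cooccurrence"),
            improvement=d.get("improvement"),
            binding_subrule=tuple(d["binding_subrule"])
            if d.get("binding_subrule") is not None
            else None,
        )


def _packed_columns(matrix: IndicatorMatrix) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-item packed carrier bitsets plus the packed death bitset."""
    packed = {
        name: np.packbits(matrix.items[name].to_numpy(dtype=bool))
        for name in matrix.item_names
    }
    died = np.packbits(matrix.died.astype(bool))
    return packed, died


def _popcount(bits: np.ndarray) -> int:
    return int(np.bitwise_count(bits).sum())


def mine_frequent_antecedents(
    matrix: IndicatorMatrix, config: MiningConfig
) -> list[ItemSet]:
    """All itemsets of size 1..max_order meeting the support floor.

    Levelwise Apriori with subset pruning; counting by intersecting the
    two joined parents' bitsets. Output is sorted by (order, antecedent).
    """
    if matrix.N == 0:
        raise MiningError("indicator matrix has no patients")
    floor = config.min_antecedent_count
    packed, _ = _packed_columns(matrix)

    counts = {name: int(matrix.items[name].sum()) for name in matrix.item_names}
    level = {
        (name,): packed[name] for name, c in counts.items() if c >= floor
    }
    result = [ItemSet((name,), counts[name]) for name in sorted(counts) if counts[name] >= floor]

    k = 2
    while level and k <= config.max_order:
        frequent_prev = set(level)
        keys = sorted(level)
        next_level: dict[tuple[str, ...], np.ndarray] = {}
        # Prefix join: two frequent (k-1)-sets sharing their first k-2 items.
        for i, left in enumerate(keys):
            prefix = left[:-1]
            for right in keys[i + 1 :]:
                if right[:-1] != prefix:
                    break
                candidate = left + (right[-1],)
                if any(
                    candidate[:j] + candidate[j + 1 :] not in frequent_prev
                    for j in range(len(candidate) - 2)
                ):
                    continue  # some (k-1)-subset infrequent: pruned
                bits = level[left] & level[right]
                count = _popcount(bits)
                if count >= floor:
                    next_level[candidate] = bits
        result.extend(ItemSet(its, _popcount(bits)) for its, bits in sorted(next_level.items()))
        level = next_level
        k += 1

    result.sort(key=lambda s: (s.order, s.items))
    logger.info(
        "mined %d frequent antecedents (floor %d subjects, order <= %d)",
        len(result), floor, config.max_order,
    )
    return result


def brute_force_mine(matrix: IndicatorMatrix, config: MiningConfig) -> list[ItemSet]:
    """Reference semantics: enumerate every subset of size 1..max_order.

    Guarded to <= 16 items; this is the oracle the Apriori miner is
    tested against, kept deliberately free of the levelwise machinery.
    """
    n_items = len(matrix.item_names)
    if n_items > _BRUTE_FORCE_MAX_ITEMS:
        raise MiningError(
            f"brute-force enumeration refused for {n_items} items "
            f"(limit {_BRUTE_FORCE_MAX_ITEMS})"
        )
    bools = {name: matrix.items[name].to_numpy(dtype=bool) for name in matrix.item_names}
    out = []
    for k in range(1, config.max_order + 1):
        for combo in itertools.combinations(sorted(bools), k):
            mask = np.ones(matrix.N, dtype=bool)
            for name in combo:
                mask &= bools[name]
            count = int(mask.sum())
            if count >= config.min_antecedent_count:
                out.append(ItemSet(tuple(combo), count))
    out.sort(key=lambda s: (s.order, s.items))
    return out


def lift_from_confidence(confidence: float, baseline: float) -> float:
    """Outcome-form lift: carrier mortality over baseline mortality."""
    if not 0 < baseline < 1:
        raise MiningError("baseline mortality must lie in (0, 1)")
    return confidence / baseline


def generate_rules(
    itemsets: Iterable[ItemSet],
    matrix: IndicatorMatrix,
    config: MiningConfig = MiningConfig(),
) -> list[Rule]:
    """One death-consequent rule per mined antecedent, from exact counts."""
    N, D = matrix.N, matrix.D
    if N == 0:
        raise MiningError("indicator matrix has no patients")
    baseline = D / N
    packed, died_bits = _packed_columns(matrix)
    prevalence = {name: int(matrix.items[name].sum()) / N for name in matrix.item_names}

    rules = []
    for itemset in itemsets:
        bits = packed[itemset.items[0]]
        for name in itemset.items[1:]:
            bits = bits & packed[name]
        n_x = _popcount(bits)
        if n_x == 0:
            logger.warning("excluding zero-carrier antecedent %s", itemset.items)
            continue
        if n_x != itemset.count:
            raise MiningError(
                f"itemset {itemset.items} count {itemset.count} does not match "
                f"matrix count {n_x}; was it mined from this matrix?"
            )
        n_xy = _popcount(bits & died_bits)
        confidence = n_xy / n_x
        expected = N * math.prod(prevalence[name] for name in itemset.items)
        rules.append(
            Rule(
                antecedent=itemset.items,
                n_antecedent=n_x,
                n_both=n_xy,
                coverage=n_x / N,
                confidence=confidence,
                lift_outcome=(
                    lift_from_confidence(confidence, baseline)
                    if config.lift_mode in ("outcome", "both")
                    else None
                ),
                lift_cooccurrence=(
                    n_x / expected if config.lift_mode in ("cooccurrence", "both") else None
                ),
            )
        )
    return rules


def mine_rules(
    matrix: IndicatorMatrix, config: MiningConfig = MiningConfig()
) -> list[Rule]:
    """Convenience: mine frequent antecedents and build their rules."""
    return generate_rules(mine_frequent_antecedents(matrix, config), matrix, config)


# ---------------------------------------------------------------------------
# JSON-lines serialization (full precision; rounding happens in reports)
# ---------------------------------------------------------------------------


def write_rules_jsonl(
    rules: Sequence[Rule], path: str | Path, meta: dict | None = None
) -> None:
    """Write rules as JSON lines, preceded by one ``_meta`` line (N, D, ...)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps({"_meta": meta or {}}) + "\n")
        for rule in rules:
            fh.write(json.dumps(rule.to_dict()) + "\n")


def read_rules_jsonl(path: str | Path) -> tuple[list[Rule], dict]:
    with open(path, "r", encoding="utf-8") as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    meta: dict = {}
    rules = []
    for obj in lines:
        if "_meta" in obj:
            meta = obj["_meta"]
        else:
            rules.append(Rule.from_dict(obj))
    return rules, meta
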