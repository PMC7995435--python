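"""Rule / rule-set algebra: library construction, assignment, objective.

A *rule* is a set of ≥2 events hypothesized to be minimally sufficient to
drive a tumor harboring all of them.  A *rule set* is a family-free collection
of rules (no rule a strict subset of another); each sample is assigned to at
most one rule it satisfies — always the satisfied rule with the largest
cumulative penalty in that sample, which per-sample greedy choice maximizes
the global objective

    J(RS) = sum(P) - sum(P^RS)

i.e. the total passenger penalty removed by designating assigned rules'
events as drivers.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import BinaryEventMatrix, PenaltyMatrix


class LibraryOverflowError(RuntimeError):
    """Rule library exceeded the hard cap; raise the coverage threshold."""


Rule = frozenset  # of event labels; always size >= 2


def make_rule(events) -> Rule:
    r = frozenset(events)
    if len(r) < 2:
        raise ValueError(f"a rule needs at least 2 events, got {sorted(r)}")
    return r


def rule_label(rule: Rule) -> str:
    """Serialize a rule as '+'-joined sorted event labels."""
    return "+".join(sorted(rule))


def parse_rule(text: str) -> Rule:
    return make_rule(text.split("+"))


def is_family(a: Rule, b: Rule) -> bool:
    """True iff one rule is a *strict* subset of the other."""
    return a < b or b < a


def is_valid_rule_set(rules) -> bool:
    rules = list(rules)
    for a, b in itertools.combinations(rules, 2):
        if is_family(a, b):
            return False
    return True


def default_msa(n_samples: int) -> int:
    """Minimum samples assigned: 3% of the cohort, rounded up."""
    return math.ceil(0.03 * n_samples)


@dataclass
class Assignment:
    """Per-sample rule assignment (None = null rule) and per-rule tallies."""

    sample_rule: list[Rule | None]
    n_assigned: dict[Rule, int]


@dataclass
class RuleSetEvaluation:
    J: float
    coverage: float
    n_assigned: dict[Rule, int]
    valid_msa: bool


@dataclass
class LibraryEntry:
    rule: Rule
    coverage: float  # carrier fraction
    n_carriers: int


class RuleEngine:
    """Vectorized evaluator for rule sets over a fixed (D, P) pair.

    Rules are interned to integer ids.  For each rule the engine caches the
    carrier mask and the per-sample cumulative penalty (zeroed outside
    carriers), so a rule set of size K evaluates as a K × n_samples max/sum.

    Tie-breaking: when a sample satisfies two rules with equal cumulative
    penalty, the larger rule wins; remaining ties go to the lexicographically
    smallest sorted event-label tuple.  Internally every rule set is evaluated
    with its rules ordered by that priority so a first-max argmax realizes the
    tie-break deterministically.
    """

    def __init__(self, d: BinaryEventMatrix, p: PenaltyMatrix, msa: int | None = None):
        if d.event_labels != p.event_labels or d.samples != p.samples:
            raise ValueError("D and P must share event/sample ordering")
        self.d = d
        self.p = p
        self.event_index = {lab: i for i, lab in enumerate(d.event_labels)}
        self.n_samples = len(d.samples)
        self.msa = default_msa(self.n_samples) if msa is None else int(msa)
        self.total_penalty = float(p.penalties.sum())
        # scale-equivariant normalizer: batched float32 arithmetic runs on
        # P / _pen_scale, so results are bit-identical under any uniform
        # rescaling of P (e.g. a different log base)
        positive = p.penalties[p.penalties > 0]
        self._pen_scale = float(positive.mean()) if positive.size else 1.0
        self._rules: list[Rule] = []
        self._rule_ids: dict[Rule, int] = {}
        self._masks: list[np.ndarray] = []  # bool carrier masks
        self._pens: list[np.ndarray] = []   # cumulative penalties, 0 off-carrier
        # priority key per rule id (larger rule first, then label tuple)
        self._prio_keys: list[tuple] = []
        self._pen_cache: np.ndarray | None = None
        self._rank_cache: np.ndarray | None = None

    # -- rule interning ----------------------------------------------------
    def rule_id(self, rule: Rule) -> int:
        rid = self._rule_ids.get(rule)
        if rid is not None:
            return rid
        idx = [self.event_index[e] for e in rule]
        mask = self.d.values[idx].all(axis=0)
        pen = self.p.penalties[idx].sum(axis=0) * mask
        rid = len(self._rules)
        self._rules.append(rule)
        self._rule_ids[rule] = rid
        self._masks.append(mask)
        self._pens.append(pen)
        self._prio_keys.append((-len(rule), tuple(sorted(rule))))
        self._pen_cache = None
        self._rank_cache = None
        return rid

    def _pen_matrix(self) -> np.ndarray:
        """Normalized float32 penalty-row cache for the batched paths (J
        differences far exceed float32 resolution; exact J is recomputed per
        set on demand)."""
        if self._pen_cache is None or self._pen_cache.shape[0] != len(self._pens):
            self._pen_cache = (
                (np.stack(self._pens) / self._pen_scale).astype(np.float32)
                if self._pens
                else np.zeros((0, self.n_samples), dtype=np.float32)
            )
        return self._pen_cache

    def _prio_rank(self) -> np.ndarray:
        """Total-order rank per rule id under the assignment tie-break."""
        if self._rank_cache is None or self._rank_cache.shape[0] != len(self._prio_keys):
            order = sorted(range(len(self._prio_keys)), key=self._prio_keys.__getitem__)
            rank = np.empty(len(order), dtype=np.int64)
            rank[np.array(order, dtype=np.int64)] = np.arange(len(order))
            self._rank_cache = rank
        return self._rank_cache

    def intern(self, rules) -> np.ndarray:
        return np.array([self.rule_id(r) for r in rules], dtype=np.int64)

    def rule_of(self, rid: int) -> Rule:
        return self._rules[rid]

    def _priority_order(self, ids: np.ndarray) -> np.ndarray:
        """Order rule ids by assignment priority (used within a rule set)."""
        keys = [self._prio_keys[i] for i in ids]
        order = sorted(range(len(ids)), key=lambda k: keys[k])
        return ids[np.array(order, dtype=np.int64)]

    def pen_rows(self, ids: np.ndarray, sample_idx: np.ndarray | None = None) -> np.ndarray:
        rows = np.stack([self._pens[i] for i in ids]) if len(ids) else np.zeros((0, self.n_samples))
        if sample_idx is not None:
            rows = rows[:, sample_idx]
        return rows

    def coverage_mask(self, rule: Rule) -> np.ndarray:
        return self._masks[self.rule_id(rule)]

    # -- single-set evaluation --------------------------------------------
    def assign(self, rules) -> Assignment:
        rules = list(rules)
        ids = self._priority_order(self.intern(rules))
        if len(ids) == 0:
            return Assignment([None] * self.n_samples, {})
        pens = self.pen_rows(ids)
        best = pens.max(axis=0)
        arg = pens.argmax(axis=0)
        sample_rule: list[Rule | None] = []
        n_assigned: dict[Rule, int] = {self._rules[i]: 0 for i in ids}
        for j in range(self.n_samples):
            if best[j] > 0:
                r = self._rules[ids[arg[j]]]
                sample_rule.append(r)
                n_assigned[r] += 1
            else:
                sample_rule.append(None)
        return Assignment(sample_rule, n_assigned)

    def evaluate(self, rules) -> RuleSetEvaluation:
        rules = list(rules)
        if not rules:
            return RuleSetEvaluation(0.0, 0.0, {}, True)
        assignment = self.assign(rules)
        ids = self.intern(rules)
        pens = self.pen_rows(ids)
        best = pens.max(axis=0)
        J = float(best.sum())
        coverage = float((best > 0).mean())
        valid = all(n >= self.msa for n in assignment.n_assigned.values())
        return RuleSetEvaluation(J, coverage, assignment.n_assigned, valid)

    # -- batched evaluation (hot path) ------------------------------------
    def evaluate_batch(
        self,
        sets: np.ndarray,
        sample_idx: np.ndarray | None = None,
        msa: int | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Evaluate many same-size rule sets.

        Parameters
        ----------
        sets : (B, K) int array of interned rule ids.
        sample_idx : optional sample subset (for subsampling analyses).
        msa : minimum samples assigned (defaults to the engine's msa).

        Returns ``(J, coverage, valid_msa)`` arrays of length B.
        """
        msa = self.msa if msa is None else msa
        B, K = sets.shape
        if B == 0:
            return np.zeros(0), np.zeros(0), np.zeros(0, dtype=bool)
        pen_matrix = self._pen_matrix() if sample_idx is None else self._pen_matrix()[:, sample_idx]
        S = pen_matrix.shape[1]
        # order each set's rules by priority so argmax-first == tie-break rule
        prio = self._prio_rank()
        Js = np.empty(B)
        covs = np.empty(B)
        valids = np.empty(B, dtype=bool)
        chunk = max(1, int(32_000_000 / max(K * S, 1)))
        for lo in range(0, B, chunk):
            sub = sets[lo : lo + chunk]
            b = sub.shape[0]
            order = np.argsort(prio[sub], axis=1, kind="stable")
            sub = np.take_along_axis(sub, order, axis=1)
            pens = pen_matrix[sub]  # (b, K, S)
            best = pens.max(axis=1)
            Js[lo : lo + b] = best.sum(axis=1, dtype=np.float64) * self._pen_scale
            covered = best > 0
            covs[lo : lo + b] = covered.mean(axis=1)
            # assignment counts: each sample goes to the first (priority-
            # ordered) rule attaining the max; avoids a slow strided argmax
            is_best = pens == best[:, None, :]
            taken = np.zeros((b, pens.shape[2]), dtype=bool)
            ok = np.ones(b, dtype=bool)
            for k in range(K):
                sel = is_best[:, k, :] & ~taken
                ok &= (sel & covered).sum(axis=1) >= msa
                taken |= sel
            valids[lo : lo + b] = ok
        return Js, covs, valids

    def single_rule_performance(self, rule: Rule) -> float:
        """SJ: objective of the singleton rule set {rule} (msa ignored)."""
        return float(self._pens[self.rule_id(rule)].sum())


def assign(d: BinaryEventMatrix, p: PenaltyMatrix, rules) -> Assignment:
    return RuleEngine(d, p).assign(rules)


def objective(d: BinaryEventMatrix, p: PenaltyMatrix, rules, msa: int | None = None) -> RuleSetEvaluation:
    return RuleEngine(d, p, msa=msa).evaluate(rules)


def single_rule_performance(d: BinaryEventMatrix, p: PenaltyMatrix, rule: Rule) -> float:
    return RuleEngine(d, p).single_rule_performance(rule)


# ---------------------------------------------------------------------------
# Rule library construction
# ---------------------------------------------------------------------------

def _apriori(d_values: np.ndarray, min_count: int, max_size: int, hard_cap: int):
    """Enumerate all event combinations of size 2..max_size with joint carrier
    count >= min_count, by monotone level-wise expansion."""
    n_events = d_values.shape[0]
    results: list[tuple[tuple[int, ...], int]] = []
    # level 1: frequent single events (not emitted; support for the join step)
    singles = [i for i in range(n_events) if int(d_values[i].sum()) >= min_count]
    level = [((i,), d_values[i]) for i in singles]
    size = 1
    while level and size < max_size:
        next_level = []
        # group by prefix for the canonical Apriori join
        by_prefix: dict[tuple[int, ...], list[tuple[int, np.ndarray]]] = {}
        for items, mask in level:
            by_prefix.setdefault(items[:-1], []).append((items[-1], mask))
        frequent = {items for items, _ in level}
        for prefix, tails in by_prefix.items():
            tails.sort(key=lambda t: t[0])
            for a in range(len(tails)):
                ia, mask_a = tails[a]
                for b in range(a + 1, len(tails)):
                    ib, mask_b = tails[b]
                    cand = prefix + (ia, ib)
                    if size >= 2:
                        # all k-subsets must be frequent (prune)
                        ok = all(
                            cand[:k] + cand[k + 1 :] in frequent
                            for k in range(len(cand) - 2)
                        )
                        if not ok:
                            continue
                    mask = mask_a & mask_b
                    count = int(mask.sum())
                    if count >= min_count:
                        next_level.append((cand, mask))
        level = next_level
        size += 1
        for items, mask in level:
            results.append((items, int(mask.sum())))
        if len(results) > hard_cap:
            raise LibraryOverflowError(
                f"rule library exceeded the hard cap of {hard_cap}; "
                "raise the coverage threshold"
            )
    return results


def build_rule_library(
    d: BinaryEventMatrix,
    min_coverage: float | None = None,
    max_rule_size: int = 6,
    hard_cap: int = 50_000,
    max_rules: int = 2_000,
) -> list[LibraryEntry]:
    """Enumerate candidate rules occurring in at least ``min_coverage`` of samples.

    With ``min_coverage=None`` the threshold defaults to the larger of 3% of
    the cohort and the smallest threshold that at most ``max_rules`` rules
    satisfy.  Returns entries sorted by coverage descending (ties by label).
    """
    n_samples = len(d.samples)
    values = d.values

    def run(min_count: int):
        return _apriori(values, min_count, max_rule_size, hard_cap)

    if min_coverage is not None:
        if not (0 < min_coverage < 1):
            raise ValueError("min_coverage must be in (0, 1)")
        min_count = max(1, math.ceil(min_coverage * n_samples))
        raw = run(min_count)
    else:
        min_count = max(1, math.ceil(0.03 * n_samples))
        raw = run(min_count)
        while len(raw) > max_rules and min_count < n_samples:
            min_count += 1
            raw = [(items, c) for items, c in raw if c >= min_count]
    labels = d.event_labels
    entries = [
        LibraryEntry(
            rule=frozenset(labels[i] for i in items),
            coverage=count / n_samples,
            n_carriers=count,
        )
        for items, count in raw
    ]
    entries.sort(key=lambda e: (-e.n_carriers, rule_label(e.rule)))
    return entries
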