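"""Four-phase stochastic search for the best rule set of each size K.

Phase 1 ranks the rule library by importance scores estimated from random
rule-set samples.  Phase 2 exhaustively evaluates valid (family-free) rule
sets drawn from the top of the ranking, for K = 1..10.  Phase 3 refines each
best-of-K set by swapping in rules from beyond the phase-2 pool.  Phase 4
extends the search to K = 11.. by growing the best smaller sets until no
candidate satisfies the minimum-samples-assigned (msa) constraint.  The core
rule set is the smallest best-of-K set reaching 90% of the maximum objective
and coverage across K.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .rules import (
    Rule,
    RuleEngine,
    LibraryEntry,
    is_family,
    rule_label,
)


@dataclass
class SearchConfig:
    """Tunable parameters of the four-phase search (paper-application defaults)."""

    p1_spr: int = 40            # random sets per rule per size, phase 1
    p1_cut_size: float = 0.25   # fraction of rules eliminated per iteration
    p1_stop: int = 24           # ranking finalized once this few rules remain
    p2_mnrs: int = 200_000      # max evaluated rule sets per K, phase 2
    p2_max_compute: int | None = None  # max validity-checked candidates (10x p2_mnrs)
    p3_mrns: int = 100_000      # expansion budget per K, phase 3
    p4_mrns: int = 100_000      # expansion budget per K, phase 4
    k_max_search: int = 40
    k_exhaustive: int = 10      # phases 2-3 cover K up to here
    msa: int | None = None      # None -> ceil(3% of cohort)
    core_fraction: float = 0.90
    top_keep: int = 100         # per-K toplist length retained for the generalized core

    def __post_init__(self):
        if not (0 < self.p1_cut_size < 1):
            raise ValueError("p1_cut_size must be in (0, 1)")
        if self.p2_max_compute is None:
            self.p2_max_compute = 10 * self.p2_mnrs


def simulation_search_config() -> SearchConfig:
    """Reduced-cost settings used for simulation studies: half the phase
    budgets and 20 sampling repetitions per rule in phase 1."""
    return SearchConfig(
        p1_spr=20,
        p2_mnrs=100_000,
        p2_max_compute=1_000_000,
        p3_mrns=50_000,
        p4_mrns=50_000,
    )


def p1_sizes_for(n_rules: int) -> tuple[int, ...]:
    """Random rule-set sizes sampled in phase 1, by library size."""
    if n_rules <= 200:
        return (3, 5, 8)
    if n_rules <= 1000:
        return (5, 10, 15)
    return (5, 10, 20)


@dataclass
class RankedRule:
    rule: Rule
    importance: float
    eliminated_round: int | None  # None = survived to the final pass


@dataclass
class KResult:
    K: int
    best: tuple[int, ...]          # engine rule ids
    J: float
    coverage: float
    pool_size: int
    top: list[tuple[float, tuple[int, ...]]] = field(default_factory=list)


@dataclass
class SearchResults:
    engine: RuleEngine
    ranking: list[RankedRule]
    per_k: dict[int, KResult]
    k_max: int

    def ranked_rules(self) -> list[Rule]:
        return [r.rule for r in self.ranking]

    def best_rule_set(self, K: int) -> list[Rule]:
        return [self.engine.rule_of(i) for i in self.per_k[K].best]


# ---------------------------------------------------------------------------
# Phase 1: stochastic rule prioritization
# ---------------------------------------------------------------------------

def _score_pass(
    engine: RuleEngine,
    ids: np.ndarray,
    sizes: tuple[int, ...],
    spr: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One importance-scoring pass over the surviving rules.

    For each sampled rule set RS and member r, the contribution of r is the
    fractional drop in J when r is removed; per size, mean contributions are
    standardized to Z scores across rules, and the importance is the mean Z
    over sizes.
    """
    n = len(ids)
    pen_matrix = engine._pen_matrix()
    z_scores = []
    usable = [s for s in sizes if 2 <= s <= n] or ([n] if n >= 2 else [])
    for s in usable:
        # stratified sampling: each rule appears in >= spr sets of size s
        groups = []
        for _ in range(spr):
            perm = rng.permutation(n)
            for lo in range(0, n, s):
                g = perm[lo : lo + s]
                if len(g) < s:
                    others = np.setdiff1d(perm, g, assume_unique=True)
                    fill = rng.choice(others, size=s - len(g), replace=False)
                    g = np.concatenate([g, fill])
                groups.append(g)
        sets = np.array(groups)  # positions into ids
        B = sets.shape[0]
        sums = np.zeros(n)
        counts = np.zeros(n)
        chunk = max(1, int(32_000_000 / max(s * engine.n_samples, 1)))
        for lo in range(0, B, chunk):
            sub = sets[lo : lo + chunk]
            b = sub.shape[0]
            pens = pen_matrix[ids[sub]]  # (b, s, S)
            max1 = pens.max(axis=1)
            J = max1.sum(axis=1, dtype=np.float64)
            # leave-one-out drop: only the first rule attaining the max loses
            # (max1 - second_max) at that sample
            is_best = pens == max1[:, None, :]
            taken = np.zeros((b, pens.shape[2]), dtype=bool)
            masked = pens.copy()
            sel_per_rule = []
            for k in range(s):
                sel = is_best[:, k, :] & ~taken
                sel_per_rule.append(sel)
                masked[:, k, :][sel] = -np.inf
                taken |= sel
            second = np.maximum(masked.max(axis=1), 0.0)
            delta = (max1 - second).astype(np.float64)
            contrib = np.empty((b, s))
            for k in range(s):
                contrib[:, k] = (delta * sel_per_rule[k]).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(J[:, None] > 0, contrib / J[:, None], 0.0)
            np.add.at(sums, sub.ravel(), frac.ravel())
            np.add.at(counts, sub.ravel(), 1.0)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        sd = means.std()  # population SD across rules
        z = (means - means.mean()) / sd if sd > 0 else np.zeros(n)
        z_scores.append(z)
    if not z_scores:
        return np.zeros(n)
    return np.mean(z_scores, axis=0)


def phase1_rank(
    engine: RuleEngine,
    library: list[LibraryEntry],
    cfg: SearchConfig,
    rng: np.random.Generator,
) -> list[RankedRule]:
    """Iteratively eliminate low-importance rules, then rank the survivors.

    Eliminated rules keep their elimination-iteration order below survivors
    (later rounds rank higher), ties broken by their last importance score.
    """
    rules = [e.rule for e in library]
    if not rules:
        raise ValueError("empty rule library")
    ids = engine.intern(rules)
    sizes = p1_sizes_for(len(rules))
    surviving = np.arange(len(rules))
    eliminated: list[tuple[int, float, int]] = []  # (round, score, position)
    round_no = 0
    while len(surviving) > cfg.p1_stop:
        round_no += 1
        scores = _quantize6(_score_pass(engine, ids[surviving], sizes, cfg.p1_spr, rng))
        cut = max(1, int(len(surviving) * cfg.p1_cut_size))
        order = np.argsort(scores, kind="stable")  # ascending
        drop = order[:cut]
        for k in drop:
            eliminated.append((round_no, float(scores[k]), int(surviving[k])))
        keep = np.ones(len(surviving), dtype=bool)
        keep[drop] = False
        surviving = surviving[keep]
    final_scores = _quantize6(_score_pass(engine, ids[surviving], sizes, cfg.p1_spr, rng))
    ranked: list[RankedRule] = []
    surv_order = sorted(
        range(len(surviving)),
        key=lambda k: (-final_scores[k], rule_label(rules[surviving[k]])),
    )
    for k in surv_order:
        ranked.append(RankedRule(rules[surviving[k]], float(final_scores[k]), None))
    # later elimination round = better; within a round, higher score = better
    for rnd, score, pos in sorted(eliminated, key=lambda t: (-t[0], -t[1])):
        ranked.append(RankedRule(rules[pos], score, rnd))
    return ranked


# ---------------------------------------------------------------------------
# Family-compatibility helpers (event bitmasks)
# ---------------------------------------------------------------------------

class _Compat:
    """Strict-subset (family) tests, precomputed as a boolean matrix.

    Containment between all rule pairs is derived in one matmul over the
    rule × event incidence matrix; distinct rules are family members iff
    their intersection equals the smaller rule.
    """

    def __init__(self, engine: RuleEngine, rules: list[Rule]):
        self.pos = {engine.rule_id(r): k for k, r in enumerate(rules)}
        inc = np.zeros((len(rules), len(engine.event_index)), dtype=np.float32)
        sizes = np.empty(len(rules), dtype=np.int64)
        for k, r in enumerate(rules):
            sizes[k] = len(r)
            for e in r:
                inc[k, engine.event_index[e]] = 1.0
        inter = (inc @ inc.T).astype(np.int64)
        family = (inter == sizes[:, None]) | (inter == sizes[None, :])
        np.fill_diagonal(family, False)  # a rule is not its own family member
        self.matrix = ~family  # True = compatible

    def compatible(self, a: int, b: int) -> bool:
        return bool(self.matrix[self.pos[a], self.pos[b]])

    def ok_with_all(self, rid: int, others) -> bool:
        row = self.matrix[self.pos[rid]]
        return all(row[self.pos[o]] for o in others)

    def set_ok(self, ids) -> bool:
        p = [self.pos[i] for i in ids]
        return bool(self.matrix[np.ix_(p, p)].all())


# ---------------------------------------------------------------------------
# Phase 2: exhaustive evaluation over the top of the ranking
# ---------------------------------------------------------------------------

def _enumerate_pool(
    ranked_ids: list[int],
    compat: _Compat,
    K: int,
    mnrs: int,
    max_compute: int,
) -> tuple[list[tuple[int, ...]], int]:
    """Valid size-K subsets of the largest top-n prefix fitting the budget.

    Grows the prefix one rule at a time; subsets introduced by rule n are
    those containing it.  Stops before the prefix whose subsets would push
    the total beyond ``mnrs`` (or the validity-check count beyond
    ``max_compute``).  Returns (subsets, pool_size).
    """
    n_total = len(ranked_ids)
    subsets: list[tuple[int, ...]] = []
    compute = 0
    pool = 0
    # compat bitmask over prefix positions
    comp_bits: list[int] = []
    prefix_pos = [compat.pos[r] for r in ranked_ids]
    for n in range(n_total):
        rid_n = ranked_ids[n]
        row = compat.matrix[prefix_pos[n]]
        bits = 0
        for m in np.flatnonzero(row[prefix_pos[:n]]):
            bits |= 1 << int(m)
        comp_bits.append(bits)
        if K == 1:
            new = [(rid_n,)]
            compute += 1
        else:
            new = []
            budget_hit = False

            def dfs(chosen: list[int], cand_bits: int, need: int, highest: int):
                nonlocal compute, budget_hit
                if budget_hit:
                    return
                if need == 0:
                    new.append(tuple(sorted(chosen + [rid_n])))
                    if len(subsets) + len(new) > mnrs:
                        budget_hit = True
                    return
                m = highest
                while m >= 0 and not budget_hit:
                    if cand_bits >> m & 1:
                        compute += 1
                        if compute > max_compute:
                            budget_hit = True
                            return
                        dfs(
                            chosen + [ranked_ids[m]],
                            cand_bits & comp_bits[m],
                            need - 1,
                            m - 1,
                        )
                    m -= 1

            dfs([], comp_bits[n], K - 1, n - 1)
            if budget_hit:
                break
        if len(subsets) + len(new) > mnrs or compute > max_compute:
            break
        subsets.extend(new)
        pool = n + 1
    return subsets, pool


def _quantize6(J):
    """Round objective values to 6 significant digits.

    All comparisons between rule sets go through quantized J so that exact
    ties (e.g. under a uniform penalty, where J is a multiple of the fixed
    penalty) are broken by the deterministic rule-id order rather than by
    floating-point rounding noise — this keeps results invariant under
    uniform rescaling of the penalty matrix.
    """
    J = np.asarray(J, dtype=np.float64)
    mag = np.abs(J)
    with np.errstate(divide="ignore"):
        exp = np.where(mag > 0, np.floor(np.log10(np.maximum(mag, 1e-300))), 0.0)
    scale = np.power(10.0, 5 - exp)
    return np.round(J * scale) / scale


def _top_merge(
    top: list[tuple[float, tuple[int, ...]]],
    Js: np.ndarray,
    sets: list[tuple[int, ...]],
    valid: np.ndarray,
    keep: int,
) -> list[tuple[float, tuple[int, ...]]]:
    Js = np.asarray(Js, dtype=np.float64)
    Jq = _quantize6(Js)
    cand = [k for k in np.flatnonzero(valid)]
    # preselect: everything at or above the keep-th largest quantized J
    if len(cand) > keep:
        vals = Jq[cand]
        kth = np.partition(vals, len(cand) - keep)[len(cand) - keep]
        cand = [k for k in cand if Jq[k] >= kth]
    seen = {s for _, s in top}
    merged = [(float(_quantize6(J)), float(J), s) for J, s in top]
    for k in cand:
        s = sets[k]
        if s not in seen:
            merged.append((float(Jq[k]), float(Js[k]), s))
            seen.add(s)
    merged.sort(key=lambda t: (-t[0], t[2]))
    return [(J, s) for _, J, s in merged[:keep]]


def phase2_exhaustive(
    engine: RuleEngine,
    ranking: list[RankedRule],
    cfg: SearchConfig,
) -> dict[int, KResult]:
    ranked_rules = [r.rule for r in ranking]
    ranked_ids = [int(i) for i in engine.intern(ranked_rules)]
    compat = _Compat(engine, ranked_rules)
    per_k: dict[int, KResult] = {}
    for K in range(1, cfg.k_exhaustive + 1):
        sets, pool = _enumerate_pool(
            ranked_ids, compat, K, cfg.p2_mnrs, cfg.p2_max_compute
        )
        if not sets:
            continue
        arr = np.array(sets, dtype=np.int64)
        Js, covs, valids = engine.evaluate_batch(arr)
        if not valids.any():
            continue
        top = _top_merge([], Js, sets, valids, cfg.top_keep)
        bestJ, best = top[0]
        cov = covs[[i for i, s in enumerate(sets) if s == best][0]]
        per_k[K] = KResult(K, best, bestJ, float(cov), pool, top)
    return per_k


# ---------------------------------------------------------------------------
# Phase 3: neighbor rule-set expansion
# ---------------------------------------------------------------------------

def _evaluate_candidates(
    engine: RuleEngine,
    cands: list[tuple[int, ...]],
    kres: KResult,
    cfg: SearchConfig,
) -> KResult:
    if not cands:
        return kres
    arr = np.array(cands, dtype=np.int64)
    Js, covs, valids = engine.evaluate_batch(arr)
    top = _top_merge(kres.top, Js, cands, valids, cfg.top_keep)
    if not top or top[0][1] == kres.best:
        return replace(kres, top=top)
    bestJ, best = top[0]
    idx = [i for i, s in enumerate(cands) if s == best]
    if idx:
        cov = float(covs[idx[0]])
    else:  # promoted from the stored toplist; fetch its coverage
        _, c, _ = engine.evaluate_batch(np.array([best], dtype=np.int64))
        cov = float(c[0])
    return replace(kres, best=best, J=bestJ, coverage=cov, top=top)


def _max_m(n_removals: int, L: int, budget: int, limit: int) -> int:
    m = 0
    while m < limit and n_removals * math.comb(m + 1, L) <= budget:
        m += 1
    return m


def phase3_neighbors(
    engine: RuleEngine,
    per_k: dict[int, KResult],
    ranking: list[RankedRule],
    cfg: SearchConfig,
) -> dict[int, KResult]:
    ranked_rules = [r.rule for r in ranking]
    ranked_ids = [int(i) for i in engine.intern(ranked_rules)]
    compat = _Compat(engine, ranked_rules)
    refined: dict[int, KResult] = {}
    for K in sorted(per_k):
        kres = per_k[K]
        best = set(kres.best)
        outside = [rid for rid in ranked_ids[kres.pool_size:] if rid not in best]
        cands: set[tuple[int, ...]] = set()
        budget_l = max(1, cfg.p3_mrns // 3)
        for L in (1, 2, 3):
            if L > K:
                continue
            removals = list(itertools.combinations(sorted(best), L))
            m = _max_m(len(removals), L, budget_l, len(outside))
            if m < L:
                continue
            pool_l = outside[:m]
            for rem in removals:
                keep = [i for i in kres.best if i not in rem]
                fits = [a for a in pool_l if compat.ok_with_all(a, keep)]
                for add in itertools.combinations(fits, L):
                    if L > 1 and not compat.set_ok(add):
                        continue
                    cand = tuple(sorted(keep + list(add)))
                    cands.add(cand)
        # size-K sets sharing K-1 rules with the best set of size K-1
        prev = refined.get(K - 1) or per_k.get(K - 1)
        if prev is not None and len(prev.best) == K - 1:
            base = set(prev.best)
            for rid in ranked_ids:
                if rid in base:
                    continue
                if compat.ok_with_all(rid, prev.best):
                    cands.add(tuple(sorted(list(prev.best) + [rid])))
        refined[K] = _evaluate_candidates(engine, sorted(cands), kres, cfg)
    return refined


# ---------------------------------------------------------------------------
# Phase 4: extension to larger K
# ---------------------------------------------------------------------------

def phase4_extend(
    engine: RuleEngine,
    per_k: dict[int, KResult],
    ranking: list[RankedRule],
    cfg: SearchConfig,
) -> tuple[dict[int, KResult], int]:
    if not per_k:
        return per_k, 0
    ranked_rules = [r.rule for r in ranking]
    ranked_ids = [int(i) for i in engine.intern(ranked_rules)]
    compat = _Compat(engine, ranked_rules)
    out = dict(per_k)
    k_max = max(out)
    for K in range(max(out) + 1, cfg.k_max_search + 1):
        prev = out.get(K - 1)
        if prev is None:
            break
        seeds = [s for _, s in prev.top[:3]] or [prev.best]
        cands: set[tuple[int, ...]] = set()
        budget = cfg.p4_mrns
        # (a) grow each seed by one compatible rule, in rank order
        for seed in seeds:
            sset = set(seed)
            for rid in ranked_ids:
                if len(cands) >= budget:
                    break
                if rid in sset:
                    continue
                if compat.ok_with_all(rid, seed):
                    cands.add(tuple(sorted(seed + (rid,))))
        # (b) swap one seed rule for two new ones while budget remains
        remaining = budget - len(cands)
        if remaining > 0:
            for seed in seeds:
                n_rem = len(seed)
                m = _max_m(n_rem, 2, max(1, remaining // len(seeds)), len(ranked_ids))
                pool = [rid for rid in ranked_ids[:m] if rid not in seed]
                for rm in seed:
                    keep = [i for i in seed if i != rm]
                    fits = [a for a in pool if compat.ok_with_all(a, keep)]
                    for add in itertools.combinations(fits, 2):
                        if compat.compatible(add[0], add[1]):
                            cands.add(tuple(sorted(keep + list(add))))
        if not cands:
            break
        cand_list = sorted(cands)
        arr = np.array(cand_list, dtype=np.int64)
        Js, covs, valids = engine.evaluate_batch(arr)
        if not valids.any():
            break
        top = _top_merge([], Js, cand_list, valids, cfg.top_keep)
        bestJ, best = top[0]
        idx = cand_list.index(best)
        out[K] = KResult(K, best, bestJ, float(covs[idx]), prev.pool_size, top)
        k_max = K
    return out, k_max


# ---------------------------------------------------------------------------
# Core selection and driver
# ---------------------------------------------------------------------------

def select_core(per_k: dict[int, KResult], core_fraction: float = 0.90) -> int:
    """Smallest K whose best set reaches ``core_fraction`` of the maximum
    objective *and* coverage over all K.  Returns the chosen K."""
    if not per_k:
        raise ValueError("no rule set of any size available")
    j_star = max(r.J for r in per_k.values())
    c_star = max(r.coverage for r in per_k.values())
    for K in sorted(per_k):
        r = per_k[K]
        if r.J >= core_fraction * j_star and r.coverage >= core_fraction * c_star:
            return K
    return max(per_k)  # unreachable: the argmax K always qualifies


def run_search(
    engine: RuleEngine,
    library: list[LibraryEntry],
    cfg: SearchConfig,
    rng: np.random.Generator,
) -> SearchResults:
    """Phases 1-4 end to end."""
    ranking = phase1_rank(engine, library, cfg, rng)
    per_k = phase2_exhaustive(engine, ranking, cfg)
    per_k = phase3_neighbors(engine, per_k, ranking, cfg)
    per_k, k_max = phase4_extend(engine, per_k, ranking, cfg)
    return SearchResults(engine, ranking, per_k, k_max)
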