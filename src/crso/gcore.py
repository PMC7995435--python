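"""Generalized core: subsampling confidence scores for rules, trios, duos, events.

Each iteration draws a random fraction of samples (uniform on 67-85% of the
cohort, without replacement), re-evaluates the stored per-K toplists on the
subset, draws coverage and objective thresholds uniformly on 85-99% of the
subset maxima, and selects the smallest-K best set exceeding both — the
iteration's *subcore*.  Confidence of an item is the percentage of iterations
whose subcore contains it; a duo or trio counts as present when contained in
any subcore rule.  Consensus items are those with confidence strictly above
50 and, for rules, are family-free by construction (asserted every run).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .optimize import KResult
from .rules import Rule, RuleEngine, is_valid_rule_set


class ConsensusIntegrityError(RuntimeError):
    """A family pair both above the consensus threshold: implementation bug."""


@dataclass
class GCResult:
    n_iterations: int
    rule_confidence: dict[Rule, float]
    trio_confidence: dict[frozenset, float]
    duo_confidence: dict[frozenset, float]
    event_confidence: dict[str, float]
    subcores: list[list[Rule]] = field(default_factory=list)


def generalized_core(
    engine: RuleEngine,
    per_k: dict[int, KResult],
    rng: np.random.Generator,
    n_iter: int = 100,
    subset_range: tuple[float, float] = (0.67, 0.85),
    threshold_range: tuple[float, float] = (0.85, 0.99),
) -> GCResult:
    if not per_k:
        raise ValueError("no per-K results to subsample")
    n_samples = engine.n_samples
    ks = sorted(per_k)
    toplists = {K: [np.array(s, dtype=np.int64) for _, s in per_k[K].top] for K in ks}
    rule_counts: dict[Rule, int] = {}
    trio_counts: dict[frozenset, int] = {}
    duo_counts: dict[frozenset, int] = {}
    event_counts: dict[str, int] = {}
    subcores: list[list[Rule]] = []
    for _ in range(n_iter):
        frac = rng.uniform(*subset_range)
        size = int(round(frac * n_samples))
        size = min(max(size, 1), n_samples)
        idx = rng.choice(n_samples, size=size, replace=False)
        idx.sort()
        # msa applies on the subset exactly as anywhere else: rule sets whose
        # rules fall below it score 0 and can never become the subcore
        best_per_k: dict[int, tuple[float, float, np.ndarray]] = {}
        for K in ks:
            sets = toplists[K]
            if not sets:
                continue
            arr = np.stack(sets)
            Js, covs, valid = engine.evaluate_batch(arr, sample_idx=idx, msa=engine.msa)
            if not valid.any():
                continue
            Js = np.where(valid, Js, 0.0)
            covs = np.where(valid, covs, 0.0)
            b = int(np.argmax(Js))
            best_per_k[K] = (float(Js[b]), float(covs[b]), sets[b])
        if not best_per_k:  # degenerate subset: no valid set of any size
            continue
        j_star = max(v[0] for v in best_per_k.values())
        c_star = max(v[1] for v in best_per_k.values())
        j_thr = rng.uniform(*threshold_range) * j_star
        c_thr = rng.uniform(*threshold_range) * c_star
        chosen = None
        for K in sorted(best_per_k):
            J, cov, s = best_per_k[K]
            if J >= j_thr and cov >= c_thr:
                chosen = s
                break
        if chosen is None:
            # thresholds can be jointly unattainable when coverage is not
            # monotone in K; relax to the J threshold alone, then to best J
            for K in sorted(best_per_k):
                J, cov, s = best_per_k[K]
                if J >= j_thr:
                    chosen = s
                    break
        if chosen is None:
            chosen = max(best_per_k.values(), key=lambda v: v[0])[2]
        subcore = [engine.rule_of(int(i)) for i in chosen]
        subcores.append(subcore)
        events_seen: set[str] = set()
        duos_seen: set[frozenset] = set()
        trios_seen: set[frozenset] = set()
        for r in subcore:
            rule_counts[r] = rule_counts.get(r, 0) + 1
            events_seen.update(r)
            duos_seen.update(frozenset(p) for p in itertools.combinations(sorted(r), 2))
            trios_seen.update(frozenset(t) for t in itertools.combinations(sorted(r), 3))
        for e in events_seen:
            event_counts[e] = event_counts.get(e, 0) + 1
        for d in duos_seen:
            duo_counts[d] = duo_counts.get(d, 0) + 1
        for t in trios_seen:
            trio_counts[t] = trio_counts.get(t, 0) + 1
    pct = lambda c: 100.0 * c / n_iter
    return GCResult(
        n_iterations=n_iter,
        rule_confidence={r: pct(c) for r, c in rule_counts.items()},
        trio_confidence={t: pct(c) for t, c in trio_counts.items()},
        duo_confidence={d: pct(c) for d, c in duo_counts.items()},
        event_confidence={e: pct(c) for e, c in event_counts.items()},
        subcores=subcores,
    )


def consensus(gc: GCResult, threshold: float = 50.0) -> list[Rule]:
    """Rules with confidence strictly above ``threshold`` (the con-GCRs)."""
    rules = sorted(
        (r for r, c in gc.rule_confidence.items() if c > threshold),
        key=lambda r: (-gc.rule_confidence[r], tuple(sorted(r))),
    )
    if not is_valid_rule_set(rules):
        raise ConsensusIntegrityError(
            "consensus rules contain a family pair; subcore bookkeeping is broken"
        )
    return rules


def consensus_duos(gc: GCResult, threshold: float = 50.0) -> list[frozenset]:
    return sorted(
        (d for d, c in gc.duo_confidence.items() if c > threshold),
        key=lambda d: (-gc.duo_confidence[d], tuple(sorted(d))),
    )


def consensus_trios(gc: GCResult, threshold: float = 50.0) -> list[frozenset]:
    return sorted(
        (t for t, c in gc.trio_confidence.items() if c > threshold),
        key=lambda t: (-gc.trio_confidence[t], tuple(sorted(t))),
    )
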