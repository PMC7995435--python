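"""End-to-end orchestration: library → four phases → core → generalized core.

The entry point most users want is :func:`run_crso`, which takes a binary
alteration matrix ``D`` and penalty matrix ``P`` and returns the core rule
set with per-sample assignments, the consensus generalized-core rules with
confidence scores, and the per-size search results.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gcore
from .matrix import BinaryEventMatrix, PenaltyMatrix, validate_pair
from .optimize import (
    KResult,
    SearchConfig,
    SearchResults,
    run_search,
    select_core,
)
from .rules import (
    LibraryEntry,
    Rule,
    RuleEngine,
    build_rule_library,
    rule_label,
)


@dataclass
class CRSOResult:
    engine: RuleEngine
    library: list[LibraryEntry]
    search: SearchResults
    core_k: int
    core_rules: list[Rule]
    core_J: float
    core_coverage: float
    core_assignment: list[Rule | None]
    gc: gcore.GCResult
    con_gcrs: list[Rule]
    timings: dict[str, float] = field(default_factory=dict)

    # -- report tables -----------------------------------------------------
    def per_k_table(self) -> pd.DataFrame:
        rows = []
        for K in sorted(self.search.per_k):
            r = self.search.per_k[K]
            rows.append(
                {
                    "K": K,
                    "J": r.J,
                    "coverage": r.coverage,
                    "rules": " | ".join(
                        rule_label(self.engine.rule_of(i)) for i in sorted(r.best)
                    ),
                }
            )
        return pd.DataFrame(rows)

    def core_table(self) -> pd.DataFrame:
        """Core-rule report: phase-1 rank, confidence, coverage, SJ, % assigned."""
        ranking = self.search.ranked_rules()
        cov = {e.rule: e.coverage for e in self.library}
        cov_rank = {
            r: i + 1
            for i, r in enumerate(
                sorted(cov, key=lambda r: (-cov[r], rule_label(r)))
            )
        }
        sj = {r: self.engine.single_rule_performance(r) for r in cov}
        sj_rank = {
            r: i + 1
            for i, r in enumerate(sorted(sj, key=lambda r: (-sj[r], rule_label(r))))
        }
        assigned_counts = {r: 0 for r in self.core_rules}
        for r in self.core_assignment:
            if r is not None:
                assigned_counts[r] += 1
        rows = []
        union = list(self.core_rules) + [
            r for r in self.con_gcrs if r not in self.core_rules
        ]
        for r in union:
            in_core = r in self.core_rules
            in_con = r in self.con_gcrs
            n_cover = int(self.engine.coverage_mask(r).sum())
            rows.append(
                {
                    "rule": rule_label(r),
                    "core_type": "Both" if in_core and in_con else ("Core" if in_core else "Con-GCR"),
                    "p1_rank": ranking.index(r) + 1 if r in ranking else None,
                    "conf": self.gc.rule_confidence.get(r, 0.0),
                    "coverage_pct": 100.0 * cov.get(r, 0.0),
                    "coverage_rank": cov_rank.get(r),
                    "SJ": sj.get(r),
                    "SJ_rank": sj_rank.get(r),
                    "pct_assigned": (
                        100.0 * assigned_counts[r] / n_cover
                        if in_core and n_cover
                        else None
                    ),
                }
            )
        return pd.DataFrame(rows)

    def assignment_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.engine.d.samples,
                "rule": [
                    rule_label(r) if r is not None else ""
                    for r in self.core_assignment
                ],
            }
        )

    def gc_tables(self) -> dict[str, pd.DataFrame]:
        def table(conf: dict, kind: str) -> pd.DataFrame:
            items = sorted(conf.items(), key=lambda kv: (-kv[1], str(kv[0])))
            return pd.DataFrame(
                {
                    kind: [
                        rule_label(k) if isinstance(k, frozenset) else k
                        for k, _ in items
                    ],
                    "confidence": [c for _, c in items],
                }
            )

        return {
            "GCR": table(self.gc.rule_confidence, "rule"),
            "GCT": table(self.gc.trio_confidence, "trio"),
            "GCD": table(self.gc.duo_confidence, "duo"),
            "GCE": table(self.gc.event_confidence, "event"),
        }

    def summary(self) -> dict:
        """Cohort summary: sizes, core statistics, consensus count."""
        mut = sum(1 for lab in self.engine.d.event_labels if lab.endswith("-M"))
        total = len(self.engine.d.event_labels)
        mrs = (
            float(np.mean([len(r) for r in self.core_rules]))
            if self.core_rules
            else 0.0
        )
        return {
            "samples": len(self.engine.d.samples),
            "events": total,
            "events_mutation": mut,
            "events_cnv": total - mut,
            "library_size": len(self.library),
            "Kc": self.core_k,
            "core_coverage_pct": 100.0 * self.core_coverage,
            "mean_rule_size": mrs,
            "n_con_gcrs": len(self.con_gcrs),
        }


def run_crso(
    d: BinaryEventMatrix,
    p: PenaltyMatrix,
    seed: int = 0,
    cfg: SearchConfig | None = None,
    min_coverage: float | None = None,
    gc_iterations: int = 100,
    max_rule_size: int = 6,
    library_cap: int | None = 2_000,
    validate: bool = True,
) -> CRSOResult:
    """Full pipeline on a prepared (D, P) pair.

    ``min_coverage=None`` uses the adaptive default threshold (the larger of
    3% and the smallest threshold at most ``library_cap`` rules satisfy);
    passing an explicit fraction fixes the threshold and ignores the cap.
    All randomness flows from ``seed``.
    """
    if validate:
        report = validate_pair(d, p)
        if not report.consistent:
            first = report.violations[0]
            raise ValueError(
                f"(D, P) zero-alignment violated at {first[0]}/{first[1]}: {first[2]} "
                f"({len(report.violations)} cells total)"
            )
    cfg = cfg or SearchConfig()
    ss = np.random.SeedSequence(seed)
    rng_search, rng_gc = [np.random.default_rng(s) for s in ss.spawn(2)]
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    library = build_rule_library(
        d,
        min_coverage=min_coverage,
        max_rule_size=max_rule_size,
        max_rules=library_cap if library_cap else 10**9,
    )
    if not library:
        raise ValueError("no rules satisfy the coverage threshold")
    timings["library"] = time.perf_counter() - t0

    engine = RuleEngine(d, p, msa=cfg.msa)
    t0 = time.perf_counter()
    search = run_search(engine, library, cfg, rng_search)
    timings["search"] = time.perf_counter() - t0

    core_k = select_core(search.per_k, cfg.core_fraction)
    kres = search.per_k[core_k]
    core_rules = [engine.rule_of(i) for i in kres.best]
    assignment = engine.assign(core_rules)

    t0 = time.perf_counter()
    gc = gcore.generalized_core(engine, search.per_k, rng_gc, n_iter=gc_iterations)
    timings["gcore"] = time.perf_counter() - t0
    con = gcore.consensus(gc)

    return CRSOResult(
        engine=engine,
        library=library,
        search=search,
        core_k=core_k,
        core_rules=core_rules,
        core_J=kres.J,
        core_coverage=kres.coverage,
        core_assignment=assignment.sample_rule,
        gc=gc,
        con_gcrs=con,
        timings=timings,
    )


def manifest(result: CRSOResult, seed: int, config: dict) -> dict:
    """Reproducibility manifest: config snapshot, seed, input digests, timings."""
    h = hashlib.sha256()
    h.update(result.engine.d.values.tobytes())
    d_digest = h.hexdigest()
    h = hashlib.sha256()
    h.update(result.engine.p.penalties.tobytes())
    p_digest = h.hexdigest()
    return {
        "seed": seed,
        "config": config,
        "input_digests": {"D": d_digest, "P": p_digest},
        "timings_sec": result.timings,
        "core_k": result.core_k,
        "n_con_gcrs": len(result.con_gcrs),
    }
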